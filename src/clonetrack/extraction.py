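"""Barcode extraction from amplicon reads.

Turns raw amplicon FASTQ reads into collapsed, per-library barcode count
tables. A read carries a 31-bp insert (27-bp barcode + 4-bp library ID)
between constant flanking sequences; three staggered primer pairs were used
to amplify the locus, so extraction accepts any of the three flank variants.

Processing order mirrors the standard amplicon workflow: flank trimming,
exact-length filter, minimum base-quality filter, then error-correcting
collapse of barcodes within Hamming distance 1, then demultiplexing by the
4-bp library ID (with the spike-in library routed to its own stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

from clonetrack import _seq
from clonetrack.exceptions import ConfigError

#: Target-specific primer sequences flanking the barcode insert, one
#: (forward, reverse) pair per staggered primer set. On the read, the
#: 3' flank is the reverse complement of the reverse target-specific
#: sequence.
PRIMER_PAIRS: tuple[tuple[str, str], ...] = (
    ("TAGAAGGCACAGGTCGACAG", "GTCTAGACTCACTGGCCGTC"),
    ("GCAACTAGAAGGCACAGGTC", "GACTCACTGGCCGTCGTTTT"),
    ("CAACTAGAAGGCACAGGTCG", "AGACTCACTGGCCGTCGTTT"),
)

#: (flank5, flank3) as they appear on read 1, for each staggered variant.
FLANK_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (fwd, _seq.revcomp(rev)) for fwd, rev in PRIMER_PAIRS
)

#: Library-ID tags. BC3 marks spike-in control cells.
DEFAULT_LIBRARY_TAGS: Mapping[str, str] = {"ACTG": "BC1", "GTCA": "BC2", "TGAC": "BC3"}
SPIKEIN_LIBRARY = "BC3"

REJECT_NO_FLANK = "no_flank"
REJECT_LENGTH = "length"
REJECT_QUALITY = "quality"
REJECT_PATTERN = "pattern"
REJECT_UNKNOWN_TAG = "unknown_tag"


@dataclass
class BarcodeCountTable:
    """Per-sample read counts per barcode for one library."""

    sample_id: str
    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    rejected: dict[str, int] = field(default_factory=dict)
    is_spikein: bool = False

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values()) + sum(self.rejected.values())


def extract_barcode(
    sequence: str,
    qualities: Iterable[int] | None,
    flank_pairs: Iterable[tuple[str, str]] = FLANK_PAIRS,
    min_phred: int = 30,
    insert_length: int = 31,
) -> tuple[str | None, str | None]:
    """Extract the barcode insert from one read.

    Returns ``(insert, None)`` on success or ``(None, reason)`` with a typed
    rejection reason. The insert must sit between a known 5'/3' flank pair
    (any staggered variant), be exactly ``insert_length`` long, consist of
    A/C/G/T only, and have minimum base quality >= ``min_phred``.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    for flank5, flank3 in flank_pairs:
        i = sequence.find(flank5)
        if i < 0:
            continue
        start = i + len(flank5)
        j = sequence.find(flank3, start)
        if j < 0:
            continue
        insert = sequence[start:j]
        if len(insert) != insert_length:
            return None, REJECT_LENGTH
        if any(b not in "ACGT" for b in insert):
            return None, REJECT_PATTERN
        if qualities is not None:
            quals = list(qualities)[start:j]
            if quals and min(quals) < min_phred:
                return None, REJECT_QUALITY
        return insert, None
    return None, REJECT_NO_FLANK


def count_inserts(
    fastq_path,
    sample_id: str = "sample",
    flank_pairs: Iterable[tuple[str, str]] = FLANK_PAIRS,
    min_phred: int = 30,
    insert_length: int = 31,
) -> BarcodeCountTable:
    """Parse a FASTQ file and count extracted 31-bp inserts.

    Returns a table keyed by raw insert (barcode + library tag, not yet split
    or collapsed), with per-reason rejection counts. Read conservation holds:
    ``sum(counts) + sum(rejected) == number of input reads``.
    """
    table = BarcodeCountTable(sample_id=sample_id, library_id="raw")
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        insert, reason = extract_barcode(
            str(rec.seq),
            rec.letter_annotations.get("phred_quality"),
            flank_pairs=flank_pairs,
            min_phred=min_phred,
            insert_length=insert_length,
        )
        if insert is None:
            table.rejected[reason] = table.rejected.get(reason, 0) + 1
        else:
            table.counts[insert] = table.counts.get(insert, 0) + 1
    return table


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def collapse_by_edit_distance(
    counts: Mapping[str, int], max_dist: int = 1
) -> dict[str, int]:
    """Greedy error-correcting collapse of barcode counts.

    Barcodes are visited in descending read count (ties lexicographic); each
    unabsorbed barcode becomes a centroid and absorbs every remaining
    unassigned barcode within ``max_dist`` mismatches (fixed-length
    sequences, so edit distance and Hamming distance coincide). Total reads
    are conserved and the operation is idempotent.
    """
    if not counts:
        return {}
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    seqs = [s for s, _ in items]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have equal length")
    mat = _seq.encode(seqs)
    vals = np.array([c for _, c in items], dtype=np.int64)
    assigned = np.zeros(len(seqs), dtype=bool)
    out: dict[str, int] = {}
    for i in range(len(seqs)):
        if assigned[i]:
            continue
        assigned[i] = True
        d = _seq.hamming_to_all(mat[i], mat)
        members = np.flatnonzero((~assigned) & (d <= max_dist))
        assigned[members] = True
        out[seqs[i]] = int(vals[i] + vals[members].sum())
    return out


def split_by_library(
    counts: Mapping[str, int],
    library_tags: Mapping[str, str] = DEFAULT_LIBRARY_TAGS,
    sample_id: str = "sample",
    tag_length: int = 4,
    tag_at_end: bool = True,
    spikein_library: str = SPIKEIN_LIBRARY,
) -> dict[str, BarcodeCountTable]:
    """Demultiplex 31-bp inserts into per-library barcode tables.

    Each insert is split into a 27-bp barcode and a 4-bp library-ID tag
    (default: tag occupies the final 4 bases) and routed by exact tag match.
    Inserts with unknown tags land in a ``rejected`` bucket on every table.
    The spike-in library table is flagged via ``is_spikein``.
    """
    if len(set(library_tags.values())) != len(library_tags):
        raise ConfigError("duplicate library names in tag map")
    tables = {
        lib: BarcodeCountTable(
            sample_id=sample_id, library_id=lib, is_spikein=(lib == spikein_library)
        )
        for lib in library_tags.values()
    }
    unknown = 0
    for insert, n in counts.items():
        if tag_at_end:
            barcode, tag = insert[:-tag_length], insert[-tag_length:]
        else:
            tag, barcode = insert[:tag_length], insert[tag_length:]
        lib = library_tags.get(tag)
        if lib is None:
            unknown += n
            continue
        t = tables[lib]
        t.counts[barcode] = t.counts.get(barcode, 0) + n
    if unknown:
        for t in tables.values():
            t.rejected[REJECT_UNKNOWN_TAG] = unknown
    return tables


def simulate_collision_rate(
    barcodes,
    sample_size: int = 1000,
    max_hamming: int = 4,
    n_reps: int = 100,
    seed: int = 0,
) -> float:
    """Fraction of random draws containing a barcode pair within ``max_hamming``.

    Each replicate samples ``sample_size`` barcodes without replacement from
    the library (or pooled libraries) and tests all pairwise Hamming
    distances. A sufficiently diverse library keeps this fraction under 1%
    for draws of 1,000, guaranteeing that distinct observed barcodes mark
    distinct clones even after distance-1 error collapsing.
    """
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    mat = barcodes if isinstance(barcodes, np.ndarray) else _seq.encode(list(barcodes))
    if sample_size > mat.shape[0]:
        raise ValueError("sample_size exceeds library size")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        idx = rng.choice(mat.shape[0], size=sample_size, replace=False)
        if _any_pair_within(mat[idx], max_hamming):
            hits += 1
    return hits / n_reps


def _any_pair_within(mat: np.ndarray, threshold: int, chunk: int = 200) -> bool:
    n = mat.shape[0]
    for start in range(0, n, chunk):
        block = mat[start : start + chunk]
        later = mat[start + 1 :]
        if later.shape[0] == 0:
            break
        d = (block[:, None, :] != later[None, :, :]).sum(axis=2, dtype=np.int16)
        # mask the lower triangle within the block's own span
        rows = np.arange(block.shape[0])[:, None]
        cols = np.arange(later.shape[0])[None, :]
        valid = cols >= rows  # pair (start+i, start+1+j) distinct iff j >= i
        if d[valid].size and d[valid].min() <= threshold:
            return True
    return False
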