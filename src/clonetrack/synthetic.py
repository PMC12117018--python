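"""Synthetic-data generators for the whole pipeline.

Everything the analysis consumes can be generated here with the statistical
structure the real experiment produces: uniformly random 27-bp barcode
libraries with a 4-bp library ID, clone populations drawn from growth-rate
subpopulations with propagating/transient/emerging fates across passages,
spike-in ladders (10-12,500 cells), paired-end amplicon FASTQ with
substitution errors and staggered flanks, and single-cell fixtures
(cell-barcode tables with doublets and multiple integrations, metacell
partitions, similarity matrices, per-metacell expression with plantable
epithelial-to-mesenchymal gradients). Ground truth is returned alongside
every output so recovery can be tested.

All generators are deterministic under their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clonetrack import _seq
from clonetrack.exceptions import CapacityError, ConfigError
from clonetrack.extraction import DEFAULT_LIBRARY_TAGS, FLANK_PAIRS
from clonetrack.growth import SubpopulationSpec
from clonetrack.plasticity import SignatureSet

# ---------------------------------------------------------------------------
# barcode libraries


@dataclass
class BarcodeLibrary:
    """A library of unique fixed-length barcodes plus its 4-base ID tag."""

    library_id: str
    codes: np.ndarray  # int64 codes in [0, 4^length)
    length: int
    seed: int

    def __len__(self) -> int:
        return len(self.codes)

    def encoded(self) -> np.ndarray:
        """(n, length) uint8 matrix of 2-bit base codes."""
        shifts = 2 * np.arange(self.length - 1, -1, -1, dtype=np.int64)
        return ((self.codes[:, None] >> shifts[None, :]) & 3).astype(np.uint8)

    @property
    def barcodes(self) -> list[str]:
        return _seq.decode(self.encoded())


def generate_barcode_library(
    n: int, length: int = 27, library_id: str = "BC1", seed: int = 0
) -> BarcodeLibrary:
    """Draw ``n`` unique uniformly random barcodes of ``length`` bases.

    The printed barcode design is semi-random with unpublished constant
    positions; uniform sampling over {A,C,G,T}^length has collision
    properties at least as adverse, so diversity guarantees derived from it
    are conservative.
    """
    if length < 1 or length > 27:
        raise ValueError("length must be in 1..27 (int64 code space)")
    capacity = 4**length
    if n > capacity:
        raise CapacityError(f"{n} barcodes exceed the 4^{length} = {capacity} space")
    rng = np.random.default_rng(seed)
    if capacity <= max(4 * n, 1 << 20):
        codes = rng.permutation(capacity)[:n].astype(np.int64)
    else:
        codes = np.unique(rng.integers(0, capacity, size=int(n * 1.05), dtype=np.int64))
        while len(codes) < n:
            extra = rng.integers(0, capacity, size=n, dtype=np.int64)
            codes = np.unique(np.concatenate([codes, extra]))
        codes = rng.permutation(codes)[:n]
    return BarcodeLibrary(library_id=library_id, codes=codes, length=length, seed=seed)


def pool_libraries(*libraries: BarcodeLibrary) -> np.ndarray:
    """Stack the encoded barcodes of several libraries into one matrix."""
    if not libraries:
        raise ValueError("no libraries given")
    lengths = {lib.length for lib in libraries}
    if len(lengths) != 1:
        raise ValueError("libraries have differing barcode lengths")
    return np.vstack([lib.encoded() for lib in libraries])


# ---------------------------------------------------------------------------
# experiment simulation


@dataclass
class XenograftModelConfig:
    """Study conditions for one PDTX model."""

    name: str
    n_clones: int = 300
    cells_implanted: int = 100_000
    transduction_efficiency: float = 0.2
    tumor_cells: int = 10_000_000
    pct_tumor_sampled: float = 10.0
    passages: tuple[str, ...] = ("P", "S1", "S2")
    days_in_vivo: dict[str, float] = field(
        default_factory=lambda: {"P": 120.0, "S1": 130.0, "S2": 130.0}
    )
    #: probabilities over (propagating, transient, emerging) fates
    fate_probs: dict[str, float] = field(
        default_factory=lambda: {
            "propagating": 0.03,
            "transient": 0.38,
            "emerging": 0.59,
        }
    )


@dataclass
class ExperimentConfig:
    models: list[XenograftModelConfig]
    #: growth-rate subpopulations; weights must sum to 1
    subpopulations: list[SubpopulationSpec] = field(
        default_factory=lambda: [
            SubpopulationSpec(mu=5.0, weight=0.19, label="fast"),
            SubpopulationSpec(mu=15.0, weight=0.62, label="medium"),
            SubpopulationSpec(mu=40.0, weight=0.19, label="slow"),
        ]
    )
    #: spike-in ladder: known cell number -> technical replicates
    spikein_ladder: dict[int, int] = field(
        default_factory=lambda: {10: 48, 50: 48, 250: 48, 1250: 36, 5000: 24, 12500: 24}
    )


@dataclass
class SimulatedExperiment:
    """Ground truth plus the tables the pipeline consumes."""

    clones: pd.DataFrame  # model, barcode, subpopulation, mu, fate
    clone_sizes: pd.DataFrame  # model, passage, barcode, cells
    spikeins: pd.DataFrame  # barcode, known_cells, replicate
    metadata: pd.DataFrame  # per (model, passage) xenograft metadata


def simulate_experiment(
    config: ExperimentConfig, seed: int = 0
) -> SimulatedExperiment:
    """Simulate barcoded xenografts with ground-truth clone tables.

    Each clone gets a unique barcode, a growth-rate subpopulation (by
    weight) and a fate. Propagating clones appear in the primary and at
    least one secondary, transient clones in the primary only, emerging
    clones in secondaries only; with no secondary passages configured the
    emerging probability is folded into transient. Clone sizes follow the
    stochastic growth model (log2 size ~ Gamma(days, 1/mu)) and are scaled
    so a xenograft never exceeds its configured tumour size.
    """
    weights = np.array([s.weight for s in config.subpopulations])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigError(f"subpopulation weights sum to {weights.sum()}, not 1")
    fate_names = ("propagating", "transient", "emerging")
    rng = np.random.default_rng(seed)
    lib = generate_barcode_library(
        sum(m.n_clones for m in config.models), library_id="BC1",
        seed=int(rng.integers(2**31)),
    )
    all_barcodes = lib.barcodes
    offset = 0
    clone_rows, size_rows, meta_rows = [], [], []
    for model in config.models:
        probs = np.array([model.fate_probs.get(f, 0.0) for f in fate_names], dtype=float)
        if probs.sum() <= 0:
            raise ConfigError(f"model {model.name}: fate probabilities are all zero")
        secondaries = [p for p in model.passages if p != "P"]
        if not secondaries:
            # without a secondary passage neither propagation nor emergence
            # can be observed: every clone is transient
            probs = np.array([0.0, 1.0, 0.0])
        probs = probs / probs.sum()
        barcodes = all_barcodes[offset : offset + model.n_clones]
        offset += model.n_clones
        sub_idx = rng.choice(len(config.subpopulations), size=model.n_clones, p=weights)
        fates = rng.choice(3, size=model.n_clones, p=probs)
        mus = np.array([config.subpopulations[i].mu for i in sub_idx])
        # presence masks per passage: propagating clones in primary and all
        # secondaries, transient in primary only, emerging in a random
        # nonempty subset of secondaries
        presence: dict[str, np.ndarray] = {"P": fates != 2}
        for passage in secondaries:
            presence[passage] = (fates == 0) | (
                (fates == 2) & (rng.random(model.n_clones) < 0.7)
            )
        if secondaries:
            emerging = np.flatnonzero(fates == 2)
            sec_mask = np.vstack([presence[p] for p in secondaries])
            never = emerging[~sec_mask[:, emerging].any(axis=0)]
            pick = rng.integers(0, len(secondaries), size=len(never))
            for j, cl in zip(pick, never):
                presence[secondaries[j]][cl] = True
        passage_sizes: dict[str, np.ndarray] = {}
        for passage in model.passages:
            days = model.days_in_vivo[passage]
            present = presence[passage]
            log2n = rng.gamma(shape=days, scale=1.0 / mus)
            cells = np.where(present, np.maximum(1.0, 2.0**log2n), 0.0)
            total = cells.sum()
            if total > model.tumor_cells:
                cells = np.where(
                    present, np.maximum(1.0, cells * model.tumor_cells / total), 0.0
                )
            cells = np.round(cells)
            # the 1-cell floor and rounding can push the total back over the
            # cap; trim the excess from the largest clones
            excess = cells.sum() - model.tumor_cells
            while excess > 0:
                top = int(np.argmax(cells))
                take = min(excess, cells[top] - 1)
                if take <= 0:
                    break
                cells[top] -= take
                excess -= take
            passage_sizes[passage] = cells
        for i in range(model.n_clones):
            clone_rows.append(
                {
                    "model": model.name,
                    "barcode": barcodes[i],
                    "subpopulation": config.subpopulations[sub_idx[i]].label
                    or f"subpop{sub_idx[i]}",
                    "mu": mus[i],
                    "fate": fate_names[fates[i]],
                }
            )
        for passage in model.passages:
            cells = passage_sizes[passage]
            for i in np.flatnonzero(cells > 0):
                size_rows.append(
                    {
                        "model": model.name,
                        "passage": passage,
                        "barcode": barcodes[i],
                        "cells": int(cells[i]),
                    }
                )
            meta_rows.append(
                {
                    "model": model.name,
                    "passage": passage,
                    "days_in_vivo": model.days_in_vivo[passage],
                    "cells_implanted": model.cells_implanted,
                    "transduction_pct": 100 * model.transduction_efficiency,
                    "pct_tumor_sampled": model.pct_tumor_sampled,
                    "tumor_cells": model.tumor_cells,
                }
            )
    spike_lib = generate_barcode_library(
        sum(config.spikein_ladder.values()), library_id="BC3",
        seed=int(rng.integers(2**31)),
    )
    spike_rows = []
    k = 0
    for cells_level in sorted(config.spikein_ladder):
        for rep in range(config.spikein_ladder[cells_level]):
            spike_rows.append(
                {
                    "barcode": spike_lib.barcodes[k],
                    "known_cells": cells_level,
                    "replicate": rep,
                }
            )
            k += 1
    return SimulatedExperiment(
        clones=pd.DataFrame(clone_rows),
        clone_sizes=pd.DataFrame(size_rows),
        spikeins=pd.DataFrame(spike_rows),
        metadata=pd.DataFrame(meta_rows),
    )


# ---------------------------------------------------------------------------
# amplicon read simulation


@dataclass
class ReadSimConfig:
    """Sequencing-sampling parameters for the amplicon read simulator."""

    depth: int = 100_000
    error_rate: float = 0.0  # per-base substitution probability
    low_quality_rate: float = 0.0  # per-base chance of a Q20 (sub-threshold) base
    quality: int = 37
    flank_pairs: tuple[tuple[str, str], ...] = FLANK_PAIRS
    #: "multinomial" resamples reads (PCR/sequencing noise); "expected"
    #: allocates reads deterministically in proportion to cells (largest
    #: remainder), the noiseless limit used for round-trip checks
    allocation: str = "multinomial"
    seed: int = 0

    def __post_init__(self):
        if self.depth < 0:
            raise ConfigError("depth must be >= 0")
        if self.allocation not in ("multinomial", "expected"):
            raise ConfigError("allocation must be 'multinomial' or 'expected'")
        for r in (self.error_rate, self.low_quality_rate):
            if not 0 <= r < 1:
                raise ConfigError("rates must be in [0, 1)")


_TAG_BY_LIBRARY = {lib: tag for tag, lib in DEFAULT_LIBRARY_TAGS.items()}


def simulate_amplicon_fastq(
    clone_cells: pd.DataFrame,
    spikeins: pd.DataFrame,
    cfg: ReadSimConfig,
    r1_path: str | Path | None = None,
    r2_path: str | Path | None = None,
    clone_library: str = "BC1",
) -> tuple[list[str], list[str]]:
    """Simulate one sample's paired amplicon reads.

    ``clone_cells`` has columns ``barcode, cells``; ``spikeins`` has
    ``barcode, known_cells``. Reads are allocated multinomially in
    proportion to cell numbers (clones carry the clone library's 4-bp tag,
    spike-ins the BC3 tag). Each read is flank5 + 27-bp barcode + tag +
    flank3, cycling through the three staggered flank variants, with i.i.d.
    substitution errors at ``error_rate`` and constant Phred ``quality``
    except for corrupted Q20 bases at ``low_quality_rate``. Read 2 is the
    reverse complement. Returns the two FASTQ texts as line lists and
    optionally writes them.
    """
    clone_tag = _TAG_BY_LIBRARY[clone_library]
    spike_tag = _TAG_BY_LIBRARY["BC3"]
    inserts, cells = [], []
    for row in clone_cells.itertuples(index=False):
        inserts.append(row.barcode + clone_tag)
        cells.append(float(row.cells))
    for row in spikeins.itertuples(index=False):
        inserts.append(row.barcode + spike_tag)
        cells.append(float(row.known_cells))
    if cfg.depth > 0 and not inserts:
        raise ConfigError("no templates to sequence at positive depth")
    rng = np.random.default_rng(cfg.seed)
    r1_lines: list[str] = []
    r2_lines: list[str] = []
    if cfg.depth > 0:
        probs = np.array(cells) / np.sum(cells)
        if cfg.allocation == "expected":
            exact = cfg.depth * probs
            counts = np.floor(exact).astype(np.int64)
            short = cfg.depth - counts.sum()
            if short:
                top = np.argsort(-(exact - counts), kind="stable")[:short]
                counts[top] += 1
        else:
            counts = rng.multinomial(cfg.depth, probs)
        template_idx = np.repeat(np.arange(len(inserts)), counts)
        rng.shuffle(template_idx)
        variant = np.arange(cfg.depth) % len(cfg.flank_pairs)
        insert_enc = _seq.encode(inserts)
        flank5_enc = [_seq.encode([f5])[0] for f5, _ in cfg.flank_pairs]
        flank3_enc = [_seq.encode([f3])[0] for _, f3 in cfg.flank_pairs]
        read_len = len(flank5_enc[0]) + insert_enc.shape[1] + len(flank3_enc[0])
        reads = np.empty((cfg.depth, read_len), dtype=np.uint8)
        for v in range(len(cfg.flank_pairs)):
            mask = variant == v
            n_v = int(mask.sum())
            if n_v == 0:
                continue
            block = np.concatenate(
                [
                    np.broadcast_to(flank5_enc[v], (n_v, len(flank5_enc[v]))),
                    insert_enc[template_idx[mask]],
                    np.broadcast_to(flank3_enc[v], (n_v, len(flank3_enc[v]))),
                ],
                axis=1,
            )
            reads[mask] = block
        if cfg.error_rate > 0:
            err = rng.random(reads.shape) < cfg.error_rate
            # substitute with a uniformly chosen *different* base
            reads[err] = (reads[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        quals = np.full(reads.shape, cfg.quality, dtype=np.uint8)
        if cfg.low_quality_rate > 0:
            quals[rng.random(reads.shape) < cfg.low_quality_rate] = 20
        seqs = _seq.decode(reads)
        qstrs = ["".join(chr(q + 33) for q in row) for row in quals]
        for i, (s, q) in enumerate(zip(seqs, qstrs)):
            r1_lines += [f"@read{i}/1", s, "+", q]
            r2_lines += [f"@read{i}/2", _seq.revcomp(s), "+", q[::-1]]
    if r1_path is not None:
        Path(r1_path).write_text("\n".join(r1_lines) + ("\n" if r1_lines else ""))
    if r2_path is not None:
        Path(r2_path).write_text("\n".join(r2_lines) + ("\n" if r2_lines else ""))
    return r1_lines, r2_lines


# ---------------------------------------------------------------------------
# single-cell fixture


@dataclass
class SingleCellFixture:
    """A synthetic single-cell layer with ground truth attached."""

    cell_barcodes: pd.DataFrame  # cell_id, barcode, reads
    truth: pd.DataFrame  # cell_id, clone, status, metacell, passage
    membership: pd.DataFrame  # metacell, clone, passage, cells
    similarity: pd.DataFrame  # metacell x metacell, symmetric, unit diagonal
    expression: pd.DataFrame  # metacell x gene mean UMI
    signatures: SignatureSet
    chain_position: pd.Series  # latent coordinate of each metacell on [0, 1]


def simulate_single_cell_fixture(
    clones: pd.DataFrame,
    n_cells: int = 2000,
    doublet_rate: float = 0.0,
    multi_integration_rate: float = 0.0,
    n_metacells: int = 20,
    n_genes: int = 100,
    seed: int = 0,
    primary_fraction: float = 0.5,
    gradient: bool = True,
) -> SingleCellFixture:
    """Generate the single-cell inputs with planted structure.

    ``clones`` has columns ``barcode, cells`` (cell numbers weight the
    cell-to-clone assignment); the largest clone acts as the dominant
    propagating clone and spreads over all metacells, the others
    concentrate around a clone-specific home state. Metacells sit on a
    latent chain; when ``gradient`` is set, epithelial signature genes
    decline and mesenchymal genes rise along it, and the similarity matrix
    decays with chain distance so the 3-NN graph recovers the chain.

    Doublet cells carry their clone's barcode plus a cell-unique extra
    barcode; multi-integration clones carry a fixed two-barcode combination
    in every one of their cells.
    """
    if not 0 <= doublet_rate < 1 or not 0 <= multi_integration_rate < 1:
        raise ConfigError("rates must be in [0, 1)")
    if n_metacells > n_cells:
        raise ConfigError("more metacells than cells")
    rng = np.random.default_rng(seed)
    barcodes = list(clones["barcode"])
    weights = clones["cells"].to_numpy(dtype=float)
    weights = weights / weights.sum()
    n_clones = len(barcodes)
    dominant = int(np.argmax(weights))
    # reserved extra barcodes for multi-integration partners and doublets
    extra_lib = generate_barcode_library(
        n_clones + n_cells, length=27, library_id="extra",
        seed=int(rng.integers(2**31)),
    ).barcodes
    multi_clone = rng.random(n_clones) < multi_integration_rate
    clone_of_cell = rng.choice(n_clones, size=n_cells, p=weights)
    passage = np.where(rng.random(n_cells) < primary_fraction, "P", "S1")
    home = rng.random(n_clones)
    pos = np.clip(
        home[clone_of_cell] + rng.normal(0, 0.08, size=n_cells), 0, 1 - 1e-9
    )
    pos[clone_of_cell == dominant] = rng.random((clone_of_cell == dominant).sum())
    metacell = np.minimum((pos * n_metacells).astype(int), n_metacells - 1)
    is_doublet = rng.random(n_cells) < doublet_rate
    bc_rows, truth_rows = [], []
    for c in range(n_cells):
        cl = clone_of_cell[c]
        cell_id = f"cell{c:05d}"
        carried = [barcodes[cl]]
        status = "single"
        if multi_clone[cl]:
            carried.append(extra_lib[cl])  # fixed partner per clone
            status = "multi_integration"
        if is_doublet[c]:
            carried.append(extra_lib[n_clones + c])  # cell-unique partner
            status = "doublet"
        for b in carried:
            bc_rows.append(
                {"cell_id": cell_id, "barcode": b,
                 "reads": int(rng.integers(20, 200))}
            )
        truth_rows.append(
            {"cell_id": cell_id, "clone": barcodes[cl], "status": status,
             "metacell": int(metacell[c]), "passage": passage[c]}
        )
    truth = pd.DataFrame(truth_rows)
    membership = (
        truth.groupby(["metacell", "clone", "passage"], as_index=False)
        .size()
        .rename(columns={"size": "cells"})
    )
    x = (np.arange(n_metacells) + 0.5) / n_metacells
    sim = np.exp(-np.abs(x[:, None] - x[None, :]) * n_metacells / 2.0)
    np.fill_diagonal(sim, 1.0)
    mc_ids = [f"mc{j:03d}" for j in range(n_metacells)]
    membership["metacell"] = [mc_ids[j] for j in membership["metacell"]]
    truth["metacell"] = [mc_ids[j] for j in truth["metacell"]]
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    n_sig = max(3, n_genes // 10)
    epi = genes[:n_sig]
    mes = genes[n_sig : 2 * n_sig]
    base = rng.lognormal(mean=-1.0, sigma=0.5, size=(n_metacells, n_genes))
    expr = base * (1 + 0.3 * rng.normal(size=(n_metacells, n_genes)))
    expr = np.maximum(expr, 0.0)
    if gradient:
        expr[:, :n_sig] *= (1.5 - x[:, None]) ** 2  # epithelial: high at chain start
        expr[:, n_sig : 2 * n_sig] *= (0.5 + x[:, None]) ** 2  # mesenchymal: rises
    # simple basal/LP/ML signature lists from the remaining genes
    rest = genes[2 * n_sig :]
    third = max(1, len(rest) // 3)
    sigs = SignatureSet(
        basal=rest[:third], lp=rest[third : 2 * third],
        ml=rest[2 * third : 3 * third], epithelial=epi, mesenchymal=mes,
    )
    return SingleCellFixture(
        cell_barcodes=pd.DataFrame(bc_rows),
        truth=truth,
        membership=membership,
        similarity=pd.DataFrame(sim, index=mc_ids, columns=mc_ids),
        expression=pd.DataFrame(expr, index=mc_ids, columns=genes),
        signatures=sigs,
        chain_position=pd.Series(x, index=mc_ids),
    )
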