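"""Single-cell layer: clones on the metacell map.

Links barcode clones to transcriptional cell states: resolves multi-barcode
cells (doublets vs multiple lentiviral integrations), builds the 3-nearest-
neighbour metacell similarity graph, measures transcriptional distance from
clone root states, clusters genes into co-expression modules and tracks
their enrichment over distance, projects clones onto epithelial signature
ternary coordinates, and runs the downsampled pseudobulk differential-
expression procedure (Mann-Whitney per gene, BH-FDR corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from clonetrack.metrics import shannon_entropy

STATUS_SINGLE = "single"
STATUS_DOUBLET = "doublet_blacklisted"
STATUS_MULTI = "multi_integration_resolved"


# ---------------------------------------------------------------------------
# barcode-cell resolution


def resolve_multibarcode_cells(
    assignments: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Resolve cells carrying >= 2 barcodes into doublets or multi-integrations.

    ``assignments`` has one row per (cell, barcode) with columns
    ``cell_id, barcode, reads``. A multi-barcode combination seen in exactly
    one cell is a likely scRNA-seq doublet and is blacklisted; the same
    combination repeated across >= 2 cells marks multiple lentiviral
    integrations in one clone of origin, and all carriers are resolved to a
    single representative barcode (highest aggregate read count, ties
    lexicographic) so the clone is not counted twice.

    Returns (per-cell table with ``cell_id, status, resolved_barcode``,
    fraction of cells carrying >= 2 barcodes).
    """
    required = {"cell_id", "barcode"}
    if not required.issubset(assignments.columns):
        raise ValueError("assignments needs cell_id and barcode columns")
    reads = (
        assignments.groupby("barcode")["reads"].sum()
        if "reads" in assignments.columns
        else pd.Series(dtype=float)
    )
    per_cell = assignments.groupby("cell_id")["barcode"].agg(frozenset)
    multi = per_cell[per_cell.map(len) >= 2]
    pattern_cells = multi.value_counts()
    rows = []
    for cell, bcs in per_cell.items():
        if len(bcs) == 1:
            rows.append((cell, STATUS_SINGLE, next(iter(bcs))))
        elif pattern_cells[bcs] == 1:
            rows.append((cell, STATUS_DOUBLET, None))
        else:
            rep = max(bcs, key=lambda b: (reads.get(b, 0), _neg_lex(b)))
            rows.append((cell, STATUS_MULTI, rep))
    table = pd.DataFrame(rows, columns=["cell_id", "status", "resolved_barcode"])
    rate = len(multi) / len(per_cell) if len(per_cell) else 0.0
    return table, rate


def _neg_lex(s: str):
    # invert lexicographic order so max() breaks read-count ties toward the
    # lexicographically smallest barcode
    return tuple(-ord(c) for c in s)


# ---------------------------------------------------------------------------
# metacell graph and distances


@dataclass
class MetacellGraph:
    """Metacell 3-NN similarity graph with clone memberships and expression."""

    graph: nx.Graph
    membership: pd.DataFrame  # columns: metacell, clone, passage, cells
    expression: pd.DataFrame | None = None  # metacells x genes, mean UMI


def build_knn_graph(similarity, k: int = 3) -> nx.Graph:
    """Undirected union of each metacell's top-k most similar neighbours.

    ``similarity`` is a square symmetric matrix (DataFrame or array); the
    diagonal is ignored. Ties are broken by ascending node id, so the graph
    is deterministic.
    """
    if isinstance(similarity, pd.DataFrame):
        nodes = list(similarity.index)
        mat = similarity.to_numpy(dtype=float)
    else:
        mat = np.asarray(similarity, dtype=float)
        nodes = list(range(mat.shape[0]))
    n = mat.shape[0]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("similarity matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 metacells")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    kk = min(k, n - 1)
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i), key=lambda j: (-mat[i, j], j)
        )
        for j in order[:kk]:
            g.add_edge(nodes[i], nodes[j], similarity=float(mat[i, j]))
    return g


def find_roots(
    membership: pd.DataFrame,
    clone,
    min_primary_cells: int = 3,
    primary_passage: str = "P",
) -> set:
    """Root cell states: metacells holding >= 3 primary-passage cells of the clone.

    Roots (distance 0) stand for the clone's early transcriptional profile.
    Returns an empty set when the clone has no qualifying metacell, in which
    case distance analysis is skipped for that clone.
    """
    sub = membership[
        (membership["clone"] == clone) & (membership["passage"] == primary_passage)
    ]
    per_mc = sub.groupby("metacell")["cells"].sum()
    return set(per_mc[per_mc >= min_primary_cells].index)


def assign_distances(graph: nx.Graph, roots) -> dict:
    """Breadth-first transcriptional distance of every metacell from the
    nearest root. Roots map to 0; unreachable metacells are absent from the
    result (callers may treat them as flagged)."""
    roots = set(roots)
    if not roots:
        raise ValueError("no root metacells")
    missing = roots - set(graph.nodes)
    if missing:
        raise ValueError(f"roots not in graph: {sorted(missing)[:5]}")
    dist = nx.multi_source_dijkstra_path_length(graph, roots, weight=None)
    return {node: int(d) for node, d in dist.items()}


# ---------------------------------------------------------------------------
# gene modules and enrichment over distance


@dataclass
class GeneModuleSet:
    """Disjoint clusters of co-expressed genes."""

    modules: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for mid, genes in self.modules.items():
            if not genes:
                raise ValueError(f"module {mid} is empty")
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"modules overlap on {sorted(overlap)[:3]}")
            seen |= set(genes)


def filter_strong_variable_genes(
    expression: pd.DataFrame, min_mean: float = 0.05, min_cv: float = 0.5
) -> pd.DataFrame:
    """Keep strongly expressed (mean >= min_mean) and highly variable
    (coefficient of variation >= min_cv) genes. Expression is metacells x
    genes (mean UMI)."""
    mean = expression.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = expression.std(axis=0, ddof=0) / mean
    keep = (mean >= min_mean) & (cv.fillna(0) >= min_cv)
    return expression.loc[:, keep]


def cluster_gene_modules(
    expression: pd.DataFrame,
    n_modules: int,
    seed: int = 0,
    min_mean: float = 0.0,
    min_cv: float = 0.0,
) -> GeneModuleSet:
    """Partition genes into co-expression modules.

    Genes passing the strong+variable filter are clustered by k-means on
    their gene-gene correlation profiles across metacells, yielding
    ``n_modules`` disjoint modules; deterministic under ``seed``.
    """
    if n_modules < 2:
        raise ValueError("n_modules must be >= 2")
    expr = filter_strong_variable_genes(expression, min_mean, min_cv)
    genes = list(expr.columns)
    if len(genes) < n_modules:
        raise ValueError(f"only {len(genes)} genes pass the filter for {n_modules} modules")
    if len(genes) == n_modules:
        return GeneModuleSet({i: [g] for i, g in enumerate(genes)})
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(expr.to_numpy(dtype=float).T)
    corr = np.nan_to_num(corr, nan=0.0)
    km = KMeans(n_clusters=n_modules, random_state=seed, n_init=10).fit(corr)
    modules: dict[int, list[str]] = {}
    for gene, lab in zip(genes, km.labels_):
        modules.setdefault(int(lab), []).append(gene)
    return GeneModuleSet(modules)


def module_enrichment_by_distance(
    expression: pd.DataFrame,
    modules: GeneModuleSet,
    distances: dict,
    baseline: str = "arithmetic",
) -> pd.DataFrame:
    """log2 fold-enrichment of each gene module at each transcriptional distance.

    For module m and distance d the statistic is
    log2(mean module-gene expression over metacells at distance d /
    mean over all distance-assigned metacells). Standard errors summarise
    the spread of per-metacell module means at each distance. Distances
    with no metacells are simply absent.
    """
    mcs = [m for m in expression.index if m in distances]
    if not mcs:
        raise ValueError("no distance-assigned metacells in expression index")
    expr = expression.loc[mcs]
    dist = np.array([distances[m] for m in mcs])
    rows = []
    for mid, genes in modules.modules.items():
        present = [g for g in genes if g in expr.columns]
        if not present:
            continue
        per_mc = expr[present].mean(axis=1).to_numpy()
        if baseline == "arithmetic":
            base = per_mc.mean()
        elif baseline == "geometric":
            base = np.exp(np.log(np.maximum(per_mc, 1e-12)).mean())
        else:
            raise ValueError("baseline must be 'arithmetic' or 'geometric'")
        for d in sorted(set(dist)):
            at_d = per_mc[dist == d]
            enr = np.log2(max(at_d.mean(), 1e-12) / max(base, 1e-12))
            se = (
                at_d.std(ddof=1) / (np.sqrt(len(at_d)) * max(at_d.mean(), 1e-12) * np.log(2))
                if len(at_d) > 1
                else np.nan
            )
            rows.append(
                {"module": mid, "distance": int(d), "log2_enrichment": float(enr),
                 "se": float(se), "n_metacells": int(len(at_d))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signatures


@dataclass
class SignatureSet:
    """Gene lists for the three normal mammary epithelial cell types
    (basal, luminal progenitor, mature luminal), plus optional epithelial
    and mesenchymal lists. Genes shared by several of the three epithelial
    lists are removed, as signatures must be cell-type specific."""

    basal: list[str]
    lp: list[str]
    ml: list[str]
    epithelial: list[str] = field(default_factory=list)
    mesenchymal: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (self.basal and self.lp and self.ml):
            raise ValueError("basal/LP/ML lists must be nonempty")
        counts: dict[str, int] = {}
        for lst in (self.basal, self.lp, self.ml):
            for g in set(lst):
                counts[g] = counts.get(g, 0) + 1
        shared = {g for g, c in counts.items() if c > 1}
        if shared:
            self.basal = [g for g in self.basal if g not in shared]
            self.lp = [g for g in self.lp if g not in shared]
            self.ml = [g for g in self.ml if g not in shared]
            if not (self.basal and self.lp and self.ml):
                raise ValueError("overlap removal emptied a signature list")


def signature_ternary(
    clone_umis: pd.Series, sigs: SignatureSet
) -> tuple[float, float, float]:
    """(basal, LP, ML) proportions of a clone's signature-gene UMIs.

    Proportions are computed over signature-gene UMIs only and sum to 1;
    they are invariant to uniform scaling of the UMI vector. A clone with
    zero signature UMIs is undefined and raises.
    """
    totals = [
        float(clone_umis.reindex(lst).fillna(0).sum())
        for lst in (sigs.basal, sigs.lp, sigs.ml)
    ]
    s = sum(totals)
    if s <= 0:
        raise ValueError("no signature-gene UMIs: ternary projection undefined")
    return tuple(t / s for t in totals)  # type: ignore[return-value]


def signature_score(cell_umis: pd.Series, genes: list[str]) -> float:
    """Fraction of a cell's UMIs falling in the signature genes.

    A deliberately simple per-cell scorer used as input to
    :func:`bimodal_threshold`; documented stand-in, not a published scorer.
    """
    total = float(cell_umis.sum())
    if total <= 0:
        raise ValueError("cell has zero UMIs")
    return float(cell_umis.reindex(genes).fillna(0).sum()) / total


def bimodal_threshold(
    scores, bw_method=None, grid_size: int = 2048, min_prominence: float = 0.05
) -> float:
    """Split point of a bimodal score distribution.

    Fits a Gaussian kernel-density estimate (Scott's rule by default) and
    returns the density minimum between the two largest modes — the
    inflection point separating, e.g., epithelial-high from epithelial-low
    cells. Modes must have prominence >= ``min_prominence`` of the density
    maximum; raises when the density has a single such mode.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 100:
        raise ValueError("need >= 100 scores for a stable density estimate")
    kde = stats.gaussian_kde(x, bw_method=bw_method)
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=min_prominence * dens.max())
    if len(peaks) < 2:
        raise ValueError("score density is unimodal: no threshold")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    a, b = sorted(top2)
    valley = a + int(np.argmin(dens[a : b + 1]))
    return float(grid[valley])


def replicate_state_correlation(frac_rep1, frac_rep2) -> float:
    """Adjusted R^2 of one replicate's per-state cell fractions on another's.

    Measures how reproducibly a clone distributes its cells over cell
    states across secondary xenograft replicates. Zero-variance input is
    undefined: returns NaN with a warning.
    """
    x = np.asarray(frac_rep1, dtype=float)
    y = np.asarray(frac_rep2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("replicate vectors must share the state index")
    if len(x) < 3:
        raise ValueError("need >= 3 states")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance state fractions: correlation undefined")
        return float("nan")
    n = len(x)
    r2 = stats.linregress(x, y).rvalue ** 2
    return float(1 - (1 - r2) * (n - 1) / (n - 2))


def clone_state_breadth(
    membership: pd.DataFrame, clone, total_metacells: int | None = None
) -> dict[str, float]:
    """Differentiation breadth of a clone over metacell states.

    Returns the number and fraction of metacells the clone contributes
    >=1 cell to, and the Shannon entropy (bits) of the clone's cell
    distribution over metacells. ``total_metacells`` defaults to the number
    of metacells appearing in the membership table.
    """
    if total_metacells is None:
        total_metacells = membership["metacell"].nunique()
    sub = membership[(membership["clone"] == clone) & (membership["cells"] > 0)]
    per_mc = sub.groupby("metacell")["cells"].sum()
    n = int(len(per_mc))
    if n == 0:
        return {"n_metacells": 0, "fraction": 0.0, "entropy": 0.0}
    fracs = per_mc.to_numpy(dtype=float)
    return {
        "n_metacells": n,
        "fraction": n / total_metacells,
        "entropy": shannon_entropy(fracs / fracs.sum()),
    }


# ---------------------------------------------------------------------------
# pseudobulk differential expression


def downsample_cells(
    counts: pd.DataFrame, target: int, seed: int = 0
) -> pd.DataFrame:
    """Downsample every cell's UMI vector to exactly ``target`` total UMIs
    (sampling without replacement within each cell)."""
    rng = np.random.default_rng(seed)
    mat = counts.to_numpy(dtype=np.int64)
    out = np.empty_like(mat)
    for i, row in enumerate(mat):
        total = row.sum()
        if total < target:
            raise ValueError(f"cell {counts.index[i]} has {total} < target {target} UMIs")
        out[i] = rng.multivariate_hypergeometric(row, target)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def pseudobulk_de(
    cells_a: pd.DataFrame,
    cells_b: pd.DataFrame,
    min_frac_cells: float = 0.5,
    min_mean_umi: float = 0.1,
    umi_floor: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Downsampled pseudobulk differential expression between two cell groups.

    Cells below ``umi_floor`` total UMIs are excluded; remaining cells are
    downsampled to the common minimum per-cell UMI total; each group is
    pooled to a pseudobulk profile and the profiles are normalised to equal
    totals. A gene is considered when it is expressed in at least
    ``min_frac_cells`` of cells of its enriched group (the group with the
    larger normalised pseudobulk value) and has at least ``min_mean_umi``
    mean UMI per cell there. Per-gene p-values come from the Mann-Whitney
    rank-sum test on per-cell downsampled counts, corrected by
    Benjamini-Hochberg FDR.

    Returns a frame indexed by gene: ``log2_enrichment, p, q, enriched_in``.
    """
    if cells_a.shape[0] < 2 or cells_b.shape[0] < 2:
        raise ValueError("need >= 2 cells per group")
    genes = cells_a.columns
    if not genes.equals(cells_b.columns):
        raise ValueError("groups must share the gene index")
    a = cells_a[cells_a.sum(axis=1) >= umi_floor]
    b = cells_b[cells_b.sum(axis=1) >= umi_floor]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("fewer than 2 cells above the UMI floor in a group")
    target = int(min(a.sum(axis=1).min(), b.sum(axis=1).min()))
    a = downsample_cells(a, target, seed=seed)
    b = downsample_cells(b, target, seed=seed + 1)
    bulk_a = a.sum(axis=0).to_numpy(dtype=float)
    bulk_b = b.sum(axis=0).to_numpy(dtype=float)
    norm_a = bulk_a / bulk_a.sum()
    norm_b = bulk_b / bulk_b.sum()
    a_np, b_np = a.to_numpy(), b.to_numpy()
    enriched_in_a = norm_a >= norm_b
    frac = np.where(
        enriched_in_a, (a_np > 0).mean(axis=0), (b_np > 0).mean(axis=0)
    )
    mean_umi = np.where(enriched_in_a, a_np.mean(axis=0), b_np.mean(axis=0))
    keep = (frac >= min_frac_cells) & (mean_umi >= min_mean_umi)
    if not keep.any():
        return pd.DataFrame(
            columns=["log2_enrichment", "p", "q", "enriched_in"]
        ).rename_axis("gene")
    with np.errstate(divide="ignore"):
        log2fc = np.log2(np.maximum(norm_a, 1e-12) / np.maximum(norm_b, 1e-12))
    res = stats.mannwhitneyu(
        a_np[:, keep], b_np[:, keep], alternative="two-sided", axis=0
    )
    pvals = np.atleast_1d(res.pvalue)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_enrichment": log2fc[keep],
            "p": pvals,
            "q": qvals,
            "enriched_in": np.where(enriched_in_a[keep], "A", "B"),
        },
        index=genes[keep],
    ).rename_axis("gene")
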