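"""Synthetic reciprocal-transplant study generator with ground-truth labels.

Emulates the 14-pool experimental layout (7 treatments x 2 replicate pools,
pool sizes 28-76 individuals) end to end:

* expression counts: negative-binomial draws around treatment-specific
  means built on the log2 scale, with planted effect structure —
  H1 genes change only the 1550-origin reaction-norm slope (pivoted at the
  975-uatm midpoint so elevation is untouched), H2 genes shift the whole
  1550-origin line (default log2 fold change -0.42), H3 genes do both, and
  "pattern" genes realize the eight-inequality helicase-like ordering of
  treatment means exactly in expectation.  Per-sample sequencing-depth
  factors are drawn log-uniform in [0.5, 2] so size-factor estimation is
  non-trivial.
* pooled SNP data: each origin lineage carries a per-site allele frequency;
  transplant pools inherit their origin lineage's frequency (allele
  frequencies are assumed unchanged over the three-week transplant).
  "Selected" sites differ by ``delta_f`` between the 400- and 1550-uatm
  lineages, consistently in both replicates.  Read counts are Binomial
  (coverage, pool frequency); optionally the pool frequency is first
  resampled from the finite pool of individuals (``individuals_then_reads``),
  which adds the classic pool-seq variance term p(1-p)/(2N).
* GO annotations: random background terms plus one term over-represented in
  a chosen gene subset by a stated factor.

Every generator consumes a single integer seed and is bit-reproducible.
Truth labels partition genes/sites and are returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import Sample, SampleDesign, TREATMENTS, sample_name, treatment_key
from .errors import ParameterError
from .expression_prep import unigene_id
from .io_formats import SyncTable

_LN2 = np.log(2.0)

#: Relative log2 offsets of the seven treatments for planted "pattern" genes,
#: scaled so the largest spread equals ``effect_pattern_log2``.  They satisfy
#: all eight strict inequalities of the co-expression filter.
PATTERN_BASE_OFFSETS = {
    "900->400": 0.6,
    "400->400": 0.5,
    "400->1550": 0.4,
    "400->900": 0.3,
    "900->900": 0.2,
    "1550->1550": 0.1,
    "1550->400": 0.0,
}

GENE_LABELS = ("H1", "H2", "H3", "pattern", "null")


# ---------------------------------------------------------------------------
# design


def generate_design(
    replicates_per_treatment: int = 2,
    pool_size_range: tuple[int, int] = (28, 76),
    seed: int = 0,
) -> SampleDesign:
    """Sample layout: 7 treatments x replicates, pool sizes drawn uniformly."""
    if replicates_per_treatment < 1:
        raise ParameterError(
            f"replicates_per_treatment must be >= 1, got {replicates_per_treatment}"
        )
    lo, hi = pool_size_range
    if not (1 <= lo <= hi):
        raise ParameterError(f"invalid pool size range {pool_size_range}")
    rng = np.random.default_rng(seed)
    rep_labels = [chr(ord("A") + i) for i in range(replicates_per_treatment)]
    samples = []
    for origin, dest in TREATMENTS:
        for rep in rep_labels:
            samples.append(
                Sample(
                    sample_id=sample_name(origin, dest, rep),
                    origin_pco2=origin,
                    destination_pco2=dest,
                    replicate=rep,
                    pool_size=int(rng.integers(lo, hi + 1)),
                )
            )
    return SampleDesign(samples=samples)


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimParams:
    """Knobs of the expression simulator; defaults emulate the study scale."""

    n_genes: int = 28879
    baseline_log2_mean: float = 5.5
    baseline_log2_sd: float = 2.5
    nb_dispersion: float = 20.0  # NB size parameter k; var = mu + mu^2/k
    frac_h1: float = 0.024
    frac_h2: float = 0.024
    frac_h3: float = 0.001
    frac_pattern: float = 0.012
    effect_h1_log2fc: float = -0.42  # endpoint-to-endpoint slope swing
    effect_h2_log2fc: float = -0.42  # whole-line elevation shift
    effect_pattern_log2: float = 0.6  # largest spread of the pattern offsets
    effect_sd_log2: float = 0.2  # per-gene SD around the planted effects
    #: alternate the sign of planted H1/H2/H3 effects gene by gene, so
    #: up- and down-regulation are balanced and scale normalization cannot
    #: absorb part of the planted signal into the size factors
    effect_sign_alternate: bool = False
    depth_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_h1, self.frac_h2, self.frac_h3, self.frac_pattern)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ParameterError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ParameterError(f"class fractions sum to {sum(fracs)} > 1")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        lo, hi = self.depth_factor_range
        if not (0 < lo <= hi):
            raise ParameterError(f"invalid depth factor range {self.depth_factor_range}")
        if self.effect_sd_log2 < 0:
            raise ParameterError("effect_sd_log2 must be >= 0")


@dataclass
class SimulatedExpression:
    counts: pd.DataFrame  # genes x samples, integer
    truth: pd.DataFrame  # gene_id -> label (and planted effect where any)
    log2_means: pd.DataFrame  # noise-free genes x 7-treatment log2 means
    depth_factors: pd.Series  # per-sample multiplicative depth
    annotation: pd.DataFrame  # per-gene component / annotation metadata


def _allocate_classes(n: int, fracs: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder allocation; within one gene of n*frac."""
    targets = {k: n * f for k, f in fracs.items()}
    counts = {k: int(np.floor(v)) for k, v in targets.items()}
    short = max(0, int(round(sum(targets.values()))) - sum(counts.values()))
    remainders = sorted(
        fracs, key=lambda k: (targets[k] - counts[k], k), reverse=True
    )
    for k in remainders[:short]:
        counts[k] += 1
    while sum(counts.values()) > n:  # guard against rounding overshoot
        biggest = max(counts, key=counts.get)
        counts[biggest] -= 1
    return counts


def nb_log2_residual_sd(mean_count: float, dispersion: float) -> float:
    """Delta-method SD of log2(X+1) for X ~ NB(mean, size=dispersion)."""
    var = mean_count + mean_count**2 / dispersion
    return float(np.sqrt(var) / ((mean_count + 1.0) * _LN2))


def simulate_counts(
    design: SampleDesign, params: ExpressionSimParams
) -> SimulatedExpression:
    """Negative-binomial count matrix with planted hypothesis structure.

    Null genes share one expected mean across all seven treatments; planted
    genes perturb only the 1550-origin line (H1 slope, H2 elevation, H3 both)
    so that the 400- and 900-origin lines stay indistinguishable in
    expectation; pattern genes realize the helicase-like mean ordering.
    """
    params.validate()
    design.require_treatments()
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    n_class = _allocate_classes(
        G,
        {
            "H1": params.frac_h1,
            "H2": params.frac_h2,
            "H3": params.frac_h3,
            "pattern": params.frac_pattern,
        },
    )
    labels = np.array(
        ["H1"] * n_class["H1"]
        + ["H2"] * n_class["H2"]
        + ["H3"] * n_class["H3"]
        + ["pattern"] * n_class["pattern"]
        + ["null"] * (G - sum(n_class.values())),
        dtype=object,
    )
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=G)
    tkeys = [treatment_key(*t) for t in TREATMENTS]
    M = np.repeat(baseline[:, None], len(tkeys), axis=1)  # (G, 7) log2 means
    col = {k: j for j, k in enumerate(tkeys)}
    effect = np.full(G, np.nan)

    def jitter(base: float, size: int) -> np.ndarray:
        e = base + rng.normal(0.0, params.effect_sd_log2, size=size)
        if params.effect_sign_alternate:
            e *= 1 - 2 * (np.arange(size) % 2)
        return e

    is_h1 = labels == "H1"
    is_h2 = labels == "H2"
    is_h3 = labels == "H3"
    is_pat = labels == "pattern"
    # H1: slope swing e pivoted at the 975-uatm midpoint of the high pair
    e1 = jitter(params.effect_h1_log2fc, is_h1.sum())
    M[is_h1, col["1550->1550"]] += e1 / 2.0
    M[is_h1, col["1550->400"]] -= e1 / 2.0
    effect[is_h1] = e1
    # H2: whole 1550-origin line shifted, no slope change
    e2 = jitter(params.effect_h2_log2fc, is_h2.sum())
    M[is_h2, col["1550->1550"]] += e2
    M[is_h2, col["1550->400"]] += e2
    effect[is_h2] = e2
    # H3: both slope and elevation change (same sign when alternating)
    e3s = jitter(params.effect_h1_log2fc, is_h3.sum())
    e3e = jitter(params.effect_h2_log2fc, is_h3.sum())
    M[is_h3, col["1550->1550"]] += e3e + e3s / 2.0
    M[is_h3, col["1550->400"]] += e3e - e3s / 2.0
    effect[is_h3] = e3e
    # pattern: fixed offsets scaled to the requested spread
    spread = max(PATTERN_BASE_OFFSETS.values())
    for k, off in PATTERN_BASE_OFFSETS.items():
        M[is_pat, col[k]] += off * params.effect_pattern_log2 / spread

    lo, hi = params.depth_factor_range
    depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design)))
    sample_ids = design.sample_ids
    treat_of_sample = [treatment_key(*s.treatment) for s in design]
    mu = depth[None, :] * 2.0 ** M[:, [col[t] for t in treat_of_sample]]
    k = params.nb_dispersion
    counts = rng.negative_binomial(n=k, p=k / (k + mu))

    components = [f"comp{i:05d}" for i in range(G)]
    annotations = [f"protein-{i:05d}" for i in range(G)]
    gene_ids = [unigene_id(c, a) for c, a in zip(components, annotations)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    counts_df.index.name = "gene_id"
    truth = pd.DataFrame(
        {"label": labels, "effect_log2": effect}, index=pd.Index(gene_ids, name="gene_id")
    )
    log2_means = pd.DataFrame(M, index=gene_ids, columns=tkeys)
    meta = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "component_id": components,
            "annotation": annotations,
        }
    ).set_index("gene_id")
    return SimulatedExpression(
        counts=counts_df,
        truth=truth,
        log2_means=log2_means,
        depth_factors=pd.Series(depth, index=sample_ids, name="depth_factor"),
        annotation=meta,
    )


def split_isoforms(
    sim: SimulatedExpression, max_isoforms: int = 3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter each Unigene's counts over 1..max_isoforms contig rows.

    Returns a contig-level count matrix plus the matching annotation table;
    collapsing the output by (component, annotation) reproduces ``sim.counts``
    exactly (counts are split multinomially, so column sums are conserved).
    """
    if max_isoforms < 1:
        raise ParameterError("max_isoforms must be >= 1")
    rng = np.random.default_rng(seed)
    counts = sim.counts.to_numpy()
    G, S = counts.shape
    n_iso = rng.integers(1, max_isoforms + 1, size=G)
    rows, contig_ids, annot_rows = [], [], []
    for g in range(G):
        comp = sim.annotation["component_id"].iloc[g]
        ann = sim.annotation["annotation"].iloc[g]
        m = int(n_iso[g])
        if m == 1:
            split = counts[g][None, :]
        else:
            w = rng.dirichlet(np.ones(m))
            split = rng.multinomial(counts[g], w).T  # (m, S)
        for j in range(m):
            contig_ids.append(f"{comp}_seq{j + 1}")
            annot_rows.append((f"{comp}_seq{j + 1}", comp, ann))
            rows.append(split[j])
    contig_counts = pd.DataFrame(
        np.asarray(rows), index=pd.Index(contig_ids, name="gene_id"),
        columns=sim.counts.columns,
    )
    annot = pd.DataFrame(
        annot_rows, columns=["contig_id", "component_id", "annotation"]
    )
    annot["go_terms"] = [[] for _ in range(len(annot))]
    return contig_counts, annot.set_index("contig_id", drop=False)


# ---------------------------------------------------------------------------
# pooled SNPs


@dataclass
class SnpSimParams:
    """Knobs of the pool-seq simulator.

    ``coverage`` is the fixed read depth per site per pool.  Under
    ``fixed_lineage_freq`` a pool's allele frequency equals its origin
    lineage's frequency; under ``individuals_then_reads`` it is first
    resampled as Binomial(2 * pool_size, lineage freq) / (2 * pool_size),
    adding the finite-pool variance term.
    """

    n_sites: int = 20000
    coverage: int = 50
    pool_freq_model: str = "fixed_lineage_freq"
    delta_f: float = 0.3
    frac_selected: float = 0.01
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    sites_per_contig: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        if self.coverage < 1:
            raise ParameterError("coverage must be >= 1")
        if self.pool_freq_model not in ("fixed_lineage_freq", "individuals_then_reads"):
            raise ParameterError(
                f"unknown pool_freq_model {self.pool_freq_model!r}"
            )
        if not (0.0 <= self.delta_f <= 1.0):
            raise ParameterError(f"delta_f must be in [0, 1], got {self.delta_f}")
        if not (0.0 <= self.frac_selected <= 1.0):
            raise ParameterError("frac_selected must be in [0, 1]")
        lo, hi = self.base_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ParameterError(f"invalid base frequency range {self.base_freq_range}")
        if lo > 1.0 - self.delta_f:
            raise ParameterError(
                "base_freq_range leaves no room for delta_f below frequency 1"
            )
        if self.sites_per_contig < 1:
            raise ParameterError("sites_per_contig must be >= 1")


@dataclass
class SimulatedSnps:
    sync: SyncTable
    truth: pd.DataFrame  # per-site contig, position, label, lineage freqs


def sample_pool_reads(
    rng: np.random.Generator,
    freq,
    pool_size,
    coverage: int,
    model: str = "fixed_lineage_freq",
) -> np.ndarray:
    """Draw alternate-allele read counts for pools with true frequency ``freq``.

    Under ``individuals_then_reads`` the pool's realized frequency is first
    drawn Binomial(2 * pool_size, freq) / (2 * pool_size); the total variance
    of the read frequency is then p(1-p) * (1/(2N) + (1 - 1/(2N))/C).
    """
    freq = np.asarray(freq, dtype=float)
    if model == "individuals_then_reads":
        copies = 2 * np.asarray(pool_size)
        realized = rng.binomial(copies, freq) / copies
    elif model == "fixed_lineage_freq":
        realized = freq
    else:
        raise ParameterError(f"unknown pool_freq_model {model!r}")
    return rng.binomial(coverage, realized)


def simulate_pool_snps(design: SampleDesign, params: SnpSimParams) -> SimulatedSnps:
    """Biallelic sync table with planted consistent 400-vs-1550 shifts.

    The reference allele occupies the A column, the alternate the T column;
    C/G/N/del columns are zero.  Truth labels mark the ``frac_selected``
    leading sites as "selected" (when ``delta_f > 0``), the rest "null".
    """
    params.validate()
    design.require_treatments()
    rng = np.random.default_rng(params.seed)
    S = params.n_sites
    n_sel = int(round(params.frac_selected * S)) if params.delta_f > 0 else 0
    selected = np.zeros(S, dtype=bool)
    selected[:n_sel] = True
    lo, hi = params.base_freq_range
    base = rng.uniform(lo, hi, size=S)
    # keep the shifted frequency inside [0, 1] for selected sites
    base[selected] = np.minimum(base[selected], 1.0 - params.delta_f)
    alt_freq = {}  # (origin, replicate) -> per-site alt-allele frequency
    reps = sorted({s.replicate for s in design})
    for origin in (400, 900, 1550):
        shift = params.delta_f if origin == 1550 else 0.0
        for rep in reps:
            f = base.copy()
            f[selected] = f[selected] + shift
            alt_freq[(origin, rep)] = f
    counts = np.zeros((S, len(design), 6), dtype=np.int64)
    for j, s in enumerate(design):
        f = alt_freq[(s.origin_pco2, s.replicate)]
        alt = sample_pool_reads(
            rng, f, s.pool_size, params.coverage, params.pool_freq_model
        )
        counts[:, j, 0] = params.coverage - alt  # reference -> A column
        counts[:, j, 1] = alt  # alternate -> T column
    spc = params.sites_per_contig
    contig_idx = np.arange(S) // spc
    contigs = np.array([f"snpc{i:06d}" for i in contig_idx], dtype=object)
    positions = (np.arange(S) % spc) * 137 + 1
    sync = SyncTable(
        contigs=contigs,
        positions=positions.astype(np.int64),
        refs=np.array(["A"] * S, dtype=object),
        counts=counts,
        sample_ids=design.sample_ids,
    )
    truth = pd.DataFrame(
        {
            "contig": contigs,
            "position": positions,
            "label": np.where(selected, "selected", "null"),
            "base_freq": base,
            "alt_freq_1550": base + np.where(selected, params.delta_f, 0.0),
        }
    )
    return SimulatedSnps(sync=sync, truth=truth)


# ---------------------------------------------------------------------------
# GO annotations


def simulate_go_annotations(
    gene_ids: list[str],
    n_terms: int = 40,
    planted: tuple[str, list[str], float] | None = None,
    background_prob: float = 0.05,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random flat GO map with one optionally over-represented term.

    ``planted = (term_id, gene_subset, enrichment_factor)`` makes the term's
    annotation probability ``enrichment_factor * background_prob`` (capped at
    1) inside the subset while the rest of the universe keeps the background
    probability.  ``enrichment_factor = 1`` plants no real signal.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ParameterError("gene universe is empty")
    if n_terms < 1:
        raise ParameterError("n_terms must be >= 1")
    if not (0.0 < background_prob <= 1.0):
        raise ParameterError("background_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    go_map: dict[str, set[str]] = {g: set() for g in gene_ids}
    mask = rng.random((len(gene_ids), n_terms)) < background_prob
    for i, g in enumerate(gene_ids):
        for j in np.flatnonzero(mask[i]):
            go_map[g].add(terms[j])
    if planted is not None:
        term_id, subset, factor = planted
        subset = list(subset)
        unknown = [g for g in subset if g not in go_map]
        if unknown:
            raise ParameterError(
                f"planted subset contains genes outside the universe: {unknown[:5]}"
            )
        if factor < 0:
            raise ParameterError("enrichment_factor must be >= 0")
        p_in = min(1.0, factor * background_prob)
        in_subset = set(subset)
        draws = rng.random(len(gene_ids))
        for i, g in enumerate(gene_ids):
            p = p_in if g in in_subset else background_prob
            go_map[g].discard(term_id)
            if draws[i] < p:
                go_map[g].add(term_id)
    return go_map


def with_seed(params, seed: int):
    """Copy a params dataclass with its ``seed`` field replaced."""
    return replace(params, seed=int(seed))
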