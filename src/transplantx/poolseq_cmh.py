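"""Replicate-stratified Cochran-Mantel-Haenszel scan of pooled allele counts.

Each testable site contributes one 2x2 table per replicate pair (stratum):
rows are the two called alleles, columns the 400-lineage and 1550-lineage
pools.  With ``a_k`` the allele-1 / 400-lineage cell of stratum k and

    E_k = row1_k * col1_k / n_k
    V_k = row1_k * row2_k * col1_k * col2_k / (n_k^2 (n_k - 1))

the statistic is ``(|sum(a_k - E_k)| - c)^2 / sum(V_k)`` with ``c = 1/2``
when the optional continuity correction is on (off by default, the classic
test), referred to a chi-square with 1 df.  Strata with any zero margin are
excluded.  The pooled-sample layout pairs the native pools replicate-wise
and treats the 400->1550 transplants as extra 400-lineage replicates and the
1550->400 transplants as extra 1550-lineage replicates, giving four strata.

Site ascertainment keeps the two alleles with the highest summed counts over
the used pools (N and deletion columns never count), and a site is testable
iff every used pool has coverage at those two alleles of at least
``min_coverage`` and the global minor-allele count is at least
``min_minor_count``.  Bonferroni correction divides alpha by the number of
*testable* sites in the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign, sample_name
from .errors import DesignError, ParameterError
from .io_formats import NUCLEOTIDES, SyncSite, SyncTable


@dataclass
class CmhResult:
    statistic: float
    p: float
    strata_used: int
    freq_diffs: list  # per-stratum allele-1 frequency difference (col1 - col2)
    testable: bool = True


@dataclass
class BiallelicCall:
    alleles: tuple[str, str]  # (major, minor) by summed counts
    counts: np.ndarray  # (n_pools_used, 2) counts at the two alleles


@dataclass
class CmhScanResult:
    table: pd.DataFrame  # one row per testable site
    n_sites: int
    n_testable: int
    alpha: float
    bonferroni_threshold: float
    significant_contigs: list[str]
    params: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum()) if len(self.table) else 0


def default_pairing(design: SampleDesign) -> list[tuple[str, str]]:
    """Replicate-wise strata: (400R, 1550R) and (400->1550R, 1550->400R)."""
    reps = sorted({s.replicate for s in design})
    pairs = []
    for rep in reps:
        pairs.append((sample_name(400, 400, rep), sample_name(1550, 1550, rep)))
    for rep in reps:
        pairs.append((sample_name(400, 1550, rep), sample_name(1550, 400, rep)))
    return pairs


def _validate_pairing(pairing, design: SampleDesign) -> None:
    if not pairing:
        raise ParameterError("pairing must contain at least one stratum")
    flat = [s for pair in pairing for s in pair]
    if len(set(flat)) != len(flat):
        raise ParameterError("each sample may be used in at most one stratum")
    known = set(design.sample_ids)
    unknown = [s for s in flat if s not in known]
    if unknown:
        raise DesignError(f"pairing names samples absent from design: {unknown}")


def _cmh_core(a, b, c, d, continuity_correction: bool):
    """Vectorized CMH over stacked strata.

    Inputs are (n_sites, K) float arrays holding the 2x2 cells
    [[a, b], [c, d]] (rows alleles, columns groups).  Returns statistic, p,
    strata_used, and the summed numerator/denominator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    valid = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    n_safe = np.where(n > 1, n, 2.0)
    E = r1 * c1 / n_safe
    V = r1 * r2 * c1 * c2 / (n_safe * n_safe * (n_safe - 1.0))
    num = np.where(valid, a - E, 0.0).sum(axis=1)
    den = np.where(valid, V, 0.0).sum(axis=1)
    strata_used = valid.sum(axis=1)
    corr = 0.5 if continuity_correction else 0.0
    shifted = np.maximum(np.abs(num) - corr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, shifted**2 / den, np.nan)
    p = np.where(den > 0, stats.chi2.sf(stat, df=1), np.nan)
    return stat, p, strata_used, den


def cmh_test(strata, continuity_correction: bool = False) -> CmhResult:
    """CMH test on a list of 2x2 tables ``[[a, b], [c, d]]``."""
    tables = np.asarray(strata, dtype=float)
    if tables.ndim != 3 or tables.shape[1:] != (2, 2):
        raise ParameterError(f"expected a (K, 2, 2) stack of tables, got {tables.shape}")
    if (tables < 0).any():
        raise ParameterError("cell counts must be non-negative")
    a = tables[None, :, 0, 0]
    b = tables[None, :, 0, 1]
    c = tables[None, :, 1, 0]
    d = tables[None, :, 1, 1]
    stat, p, used, den = _cmh_core(a, b, c, d, continuity_correction)
    col1 = tables[:, 0, 0] + tables[:, 1, 0]
    col2 = tables[:, 0, 1] + tables[:, 1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(col1 > 0, tables[:, 0, 0] / col1, np.nan)
        f2 = np.where(col2 > 0, tables[:, 0, 1] / col2, np.nan)
    testable = bool(den[0] > 0)
    return CmhResult(
        statistic=float(stat[0]) if testable else float("nan"),
        p=float(p[0]) if testable else float("nan"),
        strata_used=int(used[0]),
        freq_diffs=list(f1 - f2),
        testable=testable,
    )


def call_biallelic(
    site: SyncSite,
    pools: list[int] | None = None,
    min_minor_count: int = 2,
    min_coverage: int = 10,
) -> BiallelicCall | None:
    """Call the top-two alleles at one site, or ``None`` when untestable.

    ``pools`` selects the pool rows used (default: all).  N and deletion
    columns are never candidate alleles.  Ties in summed counts break toward
    sync column order (A, T, C, G).
    """
    counts = site.pools if pools is None else site.pools[list(pools)]
    nt = counts[:, :4]
    totals = nt.sum(axis=0)
    order = np.argsort(-totals, kind="stable")
    i1, i2 = int(order[0]), int(order[1])
    pair = nt[:, [i1, i2]]
    if totals[i2] < min_minor_count:
        return None
    if (pair.sum(axis=1) < min_coverage).any():
        return None
    return BiallelicCall(alleles=(NUCLEOTIDES[i1], NUCLEOTIDES[i2]), counts=pair)


def scan_snps(
    sync: SyncTable,
    design: SampleDesign,
    pairing: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    min_minor_count: int = 2,
    min_coverage: int = 10,
    continuity_correction: bool = False,
) -> CmhScanResult:
    """CMH-scan every testable site of a sync table, Bonferroni-corrected.

    900-uatm pools present in the table are carried through but take no part
    in the test.  The result table holds one row per testable site with the
    statistic, raw p, per-pool allele-1 frequencies and the corrected
    significance flag; ``significant_contigs`` rolls the flags up to contigs.
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if pairing is None:
        pairing = default_pairing(design)
    _validate_pairing(pairing, design)
    pool_lo = [sync.pool_index(p400) for p400, _ in pairing]
    pool_hi = [sync.pool_index(p1550) for _, p1550 in pairing]
    used = pool_lo + pool_hi
    S = sync.n_sites
    params = {
        "alpha": alpha,
        "min_minor_count": min_minor_count,
        "min_coverage": min_coverage,
        "continuity_correction": continuity_correction,
        "pairing": list(pairing),
    }
    if S == 0:
        return CmhScanResult(
            table=pd.DataFrame(),
            n_sites=0,
            n_testable=0,
            alpha=alpha,
            bonferroni_threshold=float("nan"),
            significant_contigs=[],
            params=params,
        )
    nt = sync.counts[:, :, :4]  # (S, P, 4)
    totals = nt[:, used, :].sum(axis=1)  # (S, 4)
    order = np.argsort(-totals, axis=1, kind="stable")
    i1, i2 = order[:, 0], order[:, 1]
    rows = np.arange(S)
    # per-pool counts at the two called alleles, shape (S, P)
    c1_all = np.take_along_axis(nt, i1[:, None, None], axis=2)[:, :, 0]
    c2_all = np.take_along_axis(nt, i2[:, None, None], axis=2)[:, :, 0]
    c1 = c1_all[:, used]
    c2 = c2_all[:, used]
    coverage_ok = ((c1 + c2) >= min_coverage).all(axis=1)
    minor_ok = totals[rows, i2] >= min_minor_count
    testable = coverage_ok & minor_ok
    K = len(pairing)
    a = c1_all[:, pool_lo].astype(float)
    b = c1_all[:, pool_hi].astype(float)
    c = c2_all[:, pool_lo].astype(float)
    d = c2_all[:, pool_hi].astype(float)
    stat, p, strata_used, den = _cmh_core(a, b, c, d, continuity_correction)
    testable &= den > 0
    m = int(testable.sum())
    if m == 0:
        import warnings

        warnings.warn("no testable sites in sync table", stacklevel=2)
        return CmhScanResult(
            table=pd.DataFrame(),
            n_sites=S,
            n_testable=0,
            alpha=alpha,
            bonferroni_threshold=float("nan"),
            significant_contigs=[],
            params=params,
        )
    threshold = alpha / m
    sig = np.zeros(S, dtype=bool)
    sig[testable] = p[testable] <= threshold
    idx = np.flatnonzero(testable)
    data = {
        "contig": np.asarray(sync.contigs, dtype=object)[idx],
        "position": np.asarray(sync.positions)[idx],
        "allele1": np.array(NUCLEOTIDES, dtype=object)[i1[idx]],
        "allele2": np.array(NUCLEOTIDES, dtype=object)[i2[idx]],
        "statistic": stat[idx],
        "p": p[idx],
        "strata_used": strata_used[idx],
        "significant": sig[idx],
    }
    used_ids = [pairing[k][0] for k in range(K)] + [pairing[k][1] for k in range(K)]
    freq_lo = np.where(a + c > 0, a / np.maximum(a + c, 1), np.nan)
    freq_hi = np.where(b + d > 0, b / np.maximum(b + d, 1), np.nan)
    freqs = np.concatenate([freq_lo, freq_hi], axis=1)
    for j, sid in enumerate(used_ids):
        data[f"freq1_{sid}"] = freqs[idx, j]
    table = pd.DataFrame(data).reset_index(drop=True)
    contigs = sorted(set(table.loc[table["significant"], "contig"]))
    return CmhScanResult(
        table=table,
        n_sites=S,
        n_testable=m,
        alpha=alpha,
        bonferroni_threshold=threshold,
        significant_contigs=contigs,
        params=params,
    )
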