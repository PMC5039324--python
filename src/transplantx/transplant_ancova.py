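"""Slope/elevation ANCOVA classification of reciprocal-transplant expression.

Each gene's expression is viewed as two regression lines over destination
pCO2 — one per origin lineage — and compared with a full-interaction linear
model centered at the covariate midpoint:

    y = b0 + b1*(x - mid) + b2*g + b3*g*(x - mid)

with group coding g = -1/2 for line A and +1/2 for line B, so that b2 is the
between-line difference in *elevation* (the fitted value at the midpoint of
the two destination levels) and b3 the difference in *slope* (the reaction
norm, i.e. plasticity).  Both contrasts are tested with two-sided t tests on
``n_points - 4`` residual degrees of freedom.

A gene is assigned to a hypothesis class by two such pair tests:

* plasticity pair: 400-origin line (400->400, 400->900) vs 900-origin line
  (900->900, 900->400).  The gene must show *no* significant slope or
  elevation difference here (pure plasticity between 400 and 900 uatm).
* high pair: 400-origin line (400->400, 400->1550) vs 1550-origin line
  (1550->1550, 1550->400).  Then

  - different slopes only      -> H1 (changed plasticity),
  - different elevation only   -> H2 (changed phenotype),
  - both different             -> H3,
  - otherwise                  -> none.

No multiple-testing correction is applied across genes in this screen; the
scan reports raw per-gene p-values and class labels.  Shapiro-Wilk normality
p-values of the pooled residuals are reported as a diagnostic only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign
from .errors import DesignError, InsufficientReplicationError, ParameterError

HypothesisClass = Literal["none", "H1", "H2", "H3"]

#: (origin_A, origin_B, destination levels) of the two standard line pairs.
PLASTICITY_PAIR = (400, 900, (400, 900))
HIGH_PAIR = (400, 1550, (400, 1550))


@dataclass(frozen=True)
class TransplantLine:
    """One origin lineage's expression over two destination pCO2 levels."""

    origin_pco2: int
    points: tuple  # of (destination_pco2, expression) pairs

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([p[0] for p in self.points], dtype=float)
        y = np.array([p[1] for p in self.points], dtype=float)
        return x, y


@dataclass
class PairTestResult:
    slope_diff: float  # expression units per uatm
    elevation_diff: float  # expression units at the covariate midpoint
    slope_p: float
    elevation_p: float
    residual_df: int
    normality_p: float  # Shapiro-Wilk on pooled residuals (nan if degenerate)
    degenerate: bool = False


def _shapiro_p(residuals: np.ndarray) -> float:
    r = np.asarray(residuals, dtype=float)
    if len(r) < 3 or np.ptp(r) < 1e-12 * (1 + np.abs(r).max()):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(r).pvalue)


def _pair_fit(Y: np.ndarray, x: np.ndarray, g: np.ndarray):
    """Vectorized centered-interaction OLS fit for many genes at once.

    ``Y`` is (n_points, n_genes); ``x`` the destination covariate; ``g`` the
    +-1/2 group coding.  Returns a dict of per-gene arrays plus the residual
    matrix (n_points, n_genes).
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    Y = np.asarray(Y, dtype=float)
    levels = np.unique(x)
    if len(levels) != 2:
        raise ParameterError(
            f"each line pair needs exactly two destination levels, got {levels}"
        )
    mid = levels.mean()
    xc = x - mid
    X = np.column_stack([np.ones_like(x), xc, g, g * xc])
    n = X.shape[0]
    df = n - 4
    if df < 1:
        raise InsufficientReplicationError(
            f"{n} points leave {df} residual degrees of freedom; need >= 1"
        )
    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    B = XtXi @ (X.T @ Y)  # (4, n_genes)
    R = Y - X @ B
    rss = np.einsum("ij,ij->j", R, R)
    scale = 1.0 + np.einsum("ij,ij->j", Y, Y) / n
    degenerate = rss <= 1e-24 * scale
    sigma2 = rss / df
    diag = np.diag(XtXi)[:, None]  # (4, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(diag * sigma2[None, :])
        t = B / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero residual variance: report p=0 for nonzero contrasts, 1 for zero ones
    if degenerate.any():
        btol = 1e-10 * np.sqrt(scale)[None, :]
        p_deg = np.where(np.abs(B) > btol, 0.0, 1.0)
        p = np.where(degenerate[None, :], p_deg, p)
    return {
        "coef": B,
        "p": p,
        "residuals": R,
        "df": df,
        "degenerate": degenerate,
        "mid": mid,
    }


def ancova_pair_test(lineA: TransplantLine, lineB: TransplantLine) -> PairTestResult:
    """Compare two transplant regression lines for slope and elevation."""
    xa, ya = lineA.xy()
    xb, yb = lineB.xy()
    if set(np.unique(xa)) != set(np.unique(xb)):
        raise ParameterError(
            "both lines must cover the same two destination pCO2 levels"
        )
    x = np.concatenate([xa, xb])
    g = np.concatenate([np.full(len(xa), -0.5), np.full(len(xb), +0.5)])
    Y = np.concatenate([ya, yb])[:, None]
    fit = _pair_fit(Y, x, g)
    return PairTestResult(
        slope_diff=float(fit["coef"][3, 0]),
        elevation_diff=float(fit["coef"][2, 0]),
        slope_p=float(fit["p"][3, 0]),
        elevation_p=float(fit["p"][2, 0]),
        residual_df=fit["df"],
        normality_p=_shapiro_p(fit["residuals"][:, 0]),
        degenerate=bool(fit["degenerate"][0]),
    )


def _pair_layout(
    design: SampleDesign, origin_a: int, origin_b: int, dests: tuple[int, int]
):
    """Sample ids, covariate and group coding for one line pair.

    Line A is ``origin_a`` observed at both destinations (its native level and
    the transplant), likewise line B; e.g. the high pair uses 400->400 and
    400->1550 against 1550->1550 and 1550->400.
    """
    ids, x, g = [], [], []
    for origin, code in ((origin_a, -0.5), (origin_b, +0.5)):
        for dest in dests:
            samples = design.samples_for(origin, dest)
            if not samples:
                raise DesignError(
                    f"design lacks treatment {origin}->{dest} needed for the scan"
                )
            for s in samples:
                ids.append(s.sample_id)
                x.append(float(dest))
                g.append(code)
    return ids, np.array(x), np.array(g)


def _apply_scale(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log2p1":
        return np.log2(values + 1.0)
    if scale == "raw":
        return np.asarray(values, dtype=float)
    raise ParameterError(f"unknown analysis scale {scale!r} (use 'log2p1' or 'raw')")


def _classify(
    plast_slope_p, plast_elev_p, high_slope_p, high_elev_p, alpha: float
) -> np.ndarray:
    """Vectorized hypothesis-class decision; ties at p == alpha significant."""
    precondition = (plast_slope_p > alpha) & (plast_elev_p > alpha)
    s = high_slope_p <= alpha
    e = high_elev_p <= alpha
    out = np.full(np.shape(s), "none", dtype=object)
    out[precondition & s & ~e] = "H1"
    out[precondition & ~s & e] = "H2"
    out[precondition & s & e] = "H3"
    return out


def classify_gene(
    expr: pd.Series, design: SampleDesign, alpha: float = 0.05
) -> tuple[str, dict[str, PairTestResult]]:
    """Classify a single gene's per-sample expression (already on analysis scale)."""
    results = {}
    for name, (oa, ob, dests) in (
        ("plasticity", PLASTICITY_PAIR),
        ("high", HIGH_PAIR),
    ):
        ids, x, g = _pair_layout(design, oa, ob, dests)
        try:
            y = expr.loc[ids].to_numpy(dtype=float)
        except KeyError as exc:
            raise DesignError(f"expression values missing for sample {exc}") from None
        fit = _pair_fit(y[:, None], x, g)
        results[name] = PairTestResult(
            slope_diff=float(fit["coef"][3, 0]),
            elevation_diff=float(fit["coef"][2, 0]),
            slope_p=float(fit["p"][3, 0]),
            elevation_p=float(fit["p"][2, 0]),
            residual_df=fit["df"],
            normality_p=_shapiro_p(fit["residuals"][:, 0]),
            degenerate=bool(fit["degenerate"][0]),
        )
    cls = _classify(
        np.array(results["plasticity"].slope_p),
        np.array(results["plasticity"].elevation_p),
        np.array(results["high"].slope_p),
        np.array(results["high"].elevation_p),
        alpha,
    )
    return str(cls), results


def scan_expression(
    matrix: pd.DataFrame,
    design: SampleDesign,
    alpha: float = 0.05,
    scale: str = "log2p1",
    compute_normality: bool = True,
) -> pd.DataFrame:
    """Per-gene ANCOVA scan of a (filtered, normalized) expression matrix.

    Returns one row per gene: hypothesis class, slope/elevation contrasts and
    p-values for both line pairs, and a Shapiro-Wilk normality diagnostic on
    the pooled residuals of the two fits.  Class counts are stored in
    ``result.attrs["class_counts"]``.
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    cols = [
        "hypothesis",
        "plast_slope_diff",
        "plast_elevation_diff",
        "plast_slope_p",
        "plast_elevation_p",
        "high_slope_diff",
        "high_elevation_diff",
        "high_slope_p",
        "high_elevation_p",
        "residual_df",
        "normality_p",
        "degenerate",
    ]
    if matrix.shape[0] == 0:
        out = pd.DataFrame(columns=cols)
        out.index.name = "gene_id"
        out.attrs["class_counts"] = {"none": 0, "H1": 0, "H2": 0, "H3": 0}
        return out
    fits = {}
    residual_blocks = []
    for name, (oa, ob, dests) in (
        ("plast", PLASTICITY_PAIR),
        ("high", HIGH_PAIR),
    ):
        ids, x, g = _pair_layout(design, oa, ob, dests)
        missing = [i for i in ids if i not in matrix.columns]
        if missing:
            raise DesignError(f"expression matrix lacks sample columns {missing}")
        Y = _apply_scale(matrix.loc[:, ids].to_numpy(dtype=float).T, scale)
        fits[name] = _pair_fit(Y, x, g)
        residual_blocks.append(fits[name]["residuals"])
    classes = _classify(
        fits["plast"]["p"][3],
        fits["plast"]["p"][2],
        fits["high"]["p"][3],
        fits["high"]["p"][2],
        alpha,
    )
    pooled = np.vstack(residual_blocks)
    if compute_normality:
        normality = np.array([_shapiro_p(pooled[:, j]) for j in range(pooled.shape[1])])
    else:
        normality = np.full(pooled.shape[1], np.nan)
    out = pd.DataFrame(
        {
            "hypothesis": classes,
            "plast_slope_diff": fits["plast"]["coef"][3],
            "plast_elevation_diff": fits["plast"]["coef"][2],
            "plast_slope_p": fits["plast"]["p"][3],
            "plast_elevation_p": fits["plast"]["p"][2],
            "high_slope_diff": fits["high"]["coef"][3],
            "high_elevation_diff": fits["high"]["coef"][2],
            "high_slope_p": fits["high"]["p"][3],
            "high_elevation_p": fits["high"]["p"][2],
            "residual_df": fits["high"]["df"],
            "normality_p": normality,
            "degenerate": fits["plast"]["degenerate"] | fits["high"]["degenerate"],
        },
        index=matrix.index,
    )
    out.index.name = "gene_id"
    counts = {c: int((classes == c).sum()) for c in ("none", "H1", "H2", "H3")}
    out.attrs["class_counts"] = counts
    return out
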