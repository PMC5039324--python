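"""Logical co-expression pattern filter over replicate treatment means.

Genes co-regulated with the helicase cluster share a characteristic ordering
of mean expression across the seven transplant treatments; the filter keeps
a gene iff all eight strict inequalities hold on its replicate means:

    900->400 > 400->400        400->400  > 1550->400
    400->900 > 900->900        400->1550 > 1550->1550
    400->400 > 400->900        400->1550 > 400->900
    400->900 > 1550->400       400->900  > 1550->1550

Ties fail (the rules are strict), and the decision is invariant under any
strictly increasing transform of the means, so the analysis scale does not
matter.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .design import SampleDesign, TREATMENTS, treatment_key
from .errors import DesignError, ParameterError

#: The eight (greater, lesser) treatment pairs, in the order stated above.
PATTERN_RULES: tuple[tuple[str, str], ...] = (
    ("900->400", "400->400"),
    ("400->400", "1550->400"),
    ("400->900", "900->900"),
    ("400->1550", "1550->1550"),
    ("400->400", "400->900"),
    ("400->1550", "400->900"),
    ("400->900", "1550->400"),
    ("400->900", "1550->1550"),
)


def replicate_means(matrix: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Arithmetic mean over replicate samples, per gene and treatment.

    Returns a genes x 7 DataFrame with treatment-key columns ("400->400", ...).
    """
    cols = {}
    for origin, dest in TREATMENTS:
        samples = design.samples_for(origin, dest)
        if not samples:
            raise DesignError(f"design lacks treatment {treatment_key(origin, dest)}")
        ids = [s.sample_id for s in samples]
        missing = [i for i in ids if i not in matrix.columns]
        if missing:
            raise DesignError(f"expression matrix lacks sample columns {missing}")
        cols[treatment_key(origin, dest)] = matrix.loc[:, ids].mean(axis=1)
    out = pd.DataFrame(cols, index=matrix.index)
    out.index.name = "gene_id"
    return out


def matches_pattern(means: Mapping[str, float]) -> bool:
    """True iff all eight strict inequalities hold for one gene's means."""
    needed = {t for rule in PATTERN_RULES for t in rule}
    missing = sorted(needed - set(means))
    if missing:
        raise ParameterError(f"treatment means missing: {missing}")
    values = [means[t] for t in needed]
    if not np.isfinite(values).all():
        raise ParameterError("treatment means must be finite")
    return all(means[hi] > means[lo] for hi, lo in PATTERN_RULES)


def scan_pattern(matrix: pd.DataFrame, design: SampleDesign) -> list[str]:
    """Gene ids whose replicate treatment means satisfy the full pattern."""
    means = replicate_means(matrix, design)
    mask = np.ones(len(means), dtype=bool)
    for hi, lo in PATTERN_RULES:
        mask &= means[hi].to_numpy() > means[lo].to_numpy()
    return list(means.index[mask])
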