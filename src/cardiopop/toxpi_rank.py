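"""ToxPi integration of per-phenotype PODs into a 0-1 priority score.

Each phenotype is a slice. Within a slice, a chemical's score is linear in
-log10(POD) between the slice's observed extremes:

    score = (log10 POD_max - log10 POD) / (log10 POD_max - log10 POD_min),

so the most potent chemical in a slice scores 1 and the least potent 0;
censored or inactive entries score 0, and a slice with no spread scores 0
for everyone. The overall score is the weighted mean of slice scores
(equal weights by default); chemicals are ranked in descending score with
lexicographic chemical-id tie-breaks. By default the per-chemical slice
input is the minimum donor-specific POD (most sensitive donor), matching
the use of donor-resolved PODs as the quantitative input; the population
median is available as an alternative.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotypes import PHENOTYPE_NAMES
from .population_hill import PODSet


def pod_input_matrix(
    podsets: Iterable[PODSet],
    statistic: str = "min_donor",
) -> pd.DataFrame:
    """Chemicals x phenotypes POD matrix (uM; +inf for censored).

    ``min_donor`` takes each chemical x phenotype's lowest donor-specific
    POD (posterior median per donor); ``population_median`` uses the
    median-individual POD summary.
    """
    rows: dict[str, dict[str, float]] = {}
    for ps in podsets:
        if statistic == "min_donor":
            val = float(ps.donor_pods().min()) if not ps.censored else np.inf
        elif statistic == "population_median":
            val = ps.pod_median if not ps.censored else np.inf
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        rows.setdefault(ps.chemical_id, {})[ps.phenotype] = val
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(columns=[p for p in PHENOTYPE_NAMES if p in df.columns])
    df.index.name = "chemical_id"
    return df


def toxpi_scores(
    pod_matrix: pd.DataFrame,
    weights: Mapping[str, float] | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Slice scores, overall ToxPi score and rank per chemical.

    ``pod_matrix`` is chemicals x phenotypes in uM with +inf (or NaN)
    marking censored/inactive entries. Higher scores mean lower PODs
    (higher potency); overall = weighted mean of slice scores; rank 1 is
    the highest overall score, ties broken by chemical id.
    """
    if len(pod_matrix) < 2:
        raise ValueError("need at least 2 chemicals to rank")
    pods = pod_matrix.astype(float)
    slices = pods.columns
    if weights is None:
        w = np.full(len(slices), 1.0 / len(slices))
    elif isinstance(weights, Mapping):
        w = np.array([weights[s] for s in slices], dtype=float)
        w = w / w.sum()
    else:
        w = np.asarray(list(weights), dtype=float)
        w = w / w.sum()

    scores = pd.DataFrame(0.0, index=pods.index, columns=slices)
    for s in slices:
        col = pods[s].to_numpy()
        finite = np.isfinite(col) & (col > 0)
        if finite.sum() == 0:
            continue
        logs = np.log10(col[finite])
        lo, hi = logs.min(), logs.max()
        if hi == lo:
            continue           # constant slice carries no ranking signal
        vals = np.zeros(col.size)
        vals[finite] = (hi - np.log10(col[finite])) / (hi - lo)
        scores[s] = np.clip(vals, 0.0, 1.0)

    out = scores.copy()
    out.columns = [f"slice_{s}" for s in slices]
    out["overall_score"] = scores.to_numpy() @ w
    order = out.sort_values(
        ["overall_score"], ascending=False, kind="mergesort"
    ).index.to_list()
    # stable sort then lexicographic tie-break
    order = sorted(order, key=lambda c: (-out.loc[c, "overall_score"], str(c)))
    out["rank"] = pd.Series(
        {c: i + 1 for i, c in enumerate(order)}, name="rank"
    )
    out.index.name = "chemical_id"
    return out
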