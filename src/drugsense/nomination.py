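"""Drug nomination: rank-sum testing, FDR control, effect size, consensus.

Per dataset, each drug's imputed AUC is compared between the GBM group and
the non-HGG comparison group with a two-sided Wilcoxon rank-sum test;
p-values are Benjamini-Hochberg adjusted across the drugs of that dataset.
Effect size is the Hodges-Lehmann estimate (median of all pairwise
GBM - control differences, in AUC units); negative HLE means GBM is
predicted more sensitive. A drug is *selected* in a dataset when it is
significant (q <= alpha), GBM-favoring (HLE < 0), and within the
most-negative half of the drugs passing both gates. A drug is *nominated*
overall when selected in a majority of clinical datasets and, if required,
in the avatar dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "hodges_lehmann",
    "nominate",
    "consensus",
]

# full-enumeration exact mode is O(C(n, |x|)); cap keeps it instantaneous
_EXACT_MAX_TOTAL = 20
_EXACT_MAX_GROUP = 10


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Uses midranks, so it remains valid with ties; the p-value is the
    fraction of the C(n, |x|) equally likely splits whose U statistic is at
    least as far from its null mean as the observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx, n = len(x), len(pooled)
    mu = nx * (n - nx) / 2.0 + nx * (nx + 1) / 2.0  # null mean of x's rank sum
    obs = abs(ranks[:nx].sum() - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Parameters
    ----------
    x, y
        The two samples (GBM and comparison group).
    mode
        ``"exact"`` enumerates all group assignments (valid with ties, only
        feasible for small samples); ``"normal"`` uses the tie-corrected
        normal approximation with continuity correction; ``"auto"``
        (default) picks exact when both groups have <= 10 tie-free
        observations and the pooled size is <= 20, else normal.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        small = (x.size <= _EXACT_MAX_GROUP and y.size <= _EXACT_MAX_GROUP
                 and pooled.size <= _EXACT_MAX_TOTAL)
        mode = "exact" if (small and tie_free) else "normal"
    if mode == "exact":
        if x.size + y.size > _EXACT_MAX_TOTAL:
            raise ValueError(
                f"exact mode enumerates C(n, |x|) splits; pooled size "
                f"{x.size + y.size} exceeds {_EXACT_MAX_TOTAL}")
        return _exact_permutation_p(x, y)
    if mode == "normal":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        return float(res.pvalue)
    raise ValueError(f"mode must be 'auto', 'exact' or 'normal', got {mode!r}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hodges_lehmann(x, y) -> float:
    """Hodges-Lehmann two-sample shift: median of all pairwise x_i - y_j."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(np.median(np.subtract.outer(x, y)))


@dataclass(frozen=True)
class NominationRecord:
    """Per-drug, per-dataset comparison summary."""

    drug: str
    dataset: str
    p: float
    q: float
    hle: float
    selected: bool


def nominate(imputed: pd.DataFrame, labels: pd.Series, dataset_id: str,
             group: str = "GBM", alpha: float = 0.05,
             percentile: float = 0.5, direction: str = "negative",
             mode: str = "auto") -> pd.DataFrame:
    """Score every drug of one dataset and flag the selected ones.

    Parameters
    ----------
    imputed
        Samples x drugs matrix of imputed AUC.
    labels
        Sample -> group; ``group`` (default GBM) against everything else.
    alpha
        FDR level on the BH-adjusted q.
    percentile
        Fraction of the directional significant drugs kept, ranked by most
        negative HLE (0.5 = the conventional top half); the cut is
        inclusive, ceil-rounded, with boundary ties kept.
    direction
        ``"negative"`` restricts the ranking to GBM-favoring drugs
        (HLE < 0); ``"both"`` ranks all significant drugs by |HLE| instead.

    Returns
    -------
    DataFrame with columns drug, dataset, p, q, hle, selected.
    """
    labels = labels.reindex(imputed.index)
    in_group = (labels == group).to_numpy()
    if in_group.sum() == 0 or (~in_group).sum() == 0:
        raise ValueError(f"both groups must be non-empty in dataset {dataset_id!r}")
    if imputed.shape[1] == 0:
        raise ValueError("need at least one drug")

    rows = []
    for drug in imputed.columns:
        vals = imputed[drug].to_numpy(dtype=float)
        x, y = vals[in_group], vals[~in_group]
        rows.append((drug, wilcoxon_rank_sum(x, y, mode=mode),
                     hodges_lehmann(x, y)))
    out = pd.DataFrame(rows, columns=["drug", "p", "hle"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["dataset"] = dataset_id

    sig = out["q"] <= alpha
    if direction == "negative":
        passing = out[sig & (out["hle"] < 0)]
        ranking = passing["hle"]                      # most negative first
    elif direction == "both":
        passing = out[sig]
        ranking = -passing["hle"].abs()               # largest magnitude first
    else:
        raise ValueError(f"direction must be 'negative' or 'both', got {direction!r}")

    selected = pd.Series(False, index=out.index)
    if len(passing) > 0:
        k = ceil(len(passing) * percentile)
        if k > 0:
            threshold = np.sort(ranking.to_numpy())[k - 1]
            selected.loc[passing.index[ranking <= threshold]] = True
    out["selected"] = selected
    return out[["drug", "dataset", "p", "q", "hle", "selected"]]


def consensus(records: pd.DataFrame, dataset_kinds: dict[str, str],
              min_clinical: int = 3, require_avatar: bool = True) -> pd.DataFrame:
    """Intersect per-dataset selections into final drug nominations.

    Parameters
    ----------
    records
        Concatenated ``nominate`` outputs over all datasets.
    dataset_kinds
        Dataset id -> ``"clinical"`` or ``"avatar"``.
    min_clinical
        Minimum number of clinical datasets a drug must be selected in
        (the majority rule: at least 3 of 5).
    require_avatar
        Whether avatar selection is also required for nomination.

    Returns
    -------
    DataFrame per drug: n_clinical_passed, avatar_passed, nominated, and
    clinical_only (passed the clinical majority but failed the avatar gate).
    """
    clinical_ids = [d for d, k in dataset_kinds.items() if k == "clinical"]
    avatar_ids = [d for d, k in dataset_kinds.items() if k == "avatar"]
    if not clinical_ids:
        raise ValueError("at least one clinical dataset is required")
    unknown = set(records["dataset"]) - set(dataset_kinds)
    if unknown:
        raise ValueError(f"datasets without a kind tag: {sorted(unknown)}")

    sel = records.pivot_table(index="drug", columns="dataset",
                              values="selected", aggfunc="any", fill_value=False)
    n_clin = sel.reindex(columns=clinical_ids, fill_value=False).sum(axis=1).astype(int)
    avatar_passed = (
        sel.reindex(columns=avatar_ids, fill_value=False).any(axis=1)
        if avatar_ids else pd.Series(False, index=sel.index)
    )
    clinical_ok = n_clin >= min_clinical
    nominated = clinical_ok & (avatar_passed if require_avatar else True)
    return pd.DataFrame({
        "drug": sel.index,
        "n_clinical_passed": n_clin.to_numpy(),
        "avatar_passed": avatar_passed.to_numpy(),
        "nominated": nominated.to_numpy(),
        "clinical_only": (clinical_ok & ~avatar_passed).to_numpy(),
    }).reset_index(drop=True)
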