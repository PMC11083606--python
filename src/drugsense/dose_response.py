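"""Measured drug response: trapezoidal AUC over relative-ATP curves.

The viability readout is relative ATP (percent of untreated control)
measured in technical replicates across an increasing dose grid. Response is
summarised as the area under the empirical dose-response curve by the
trapezoidal rule; lower AUC means more killing, i.e. a more sensitive
sample. Because screening doses usually span several decades, integration
defaults to the log10-dose axis (a linear-dose trapezoid would be dominated
by the top dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DoseResponseCurve", "auc_trapezoid", "compare_measured"]


@dataclass
class DoseResponseCurve:
    """Replicated dose-response measurements for one sample and drug.

    ``doses`` are in nM and strictly increasing; ``atp`` is a
    replicate x dose matrix of relative ATP in percent of control.
    """

    doses: np.ndarray
    atp: np.ndarray
    sample_id: str = ""
    drug_id: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.atp = np.atleast_2d(np.asarray(self.atp, dtype=float))
        if self.doses.ndim != 1 or self.doses.size < 2:
            raise ValueError("need at least 2 doses")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.atp.shape[1] != self.doses.size:
            raise ValueError(
                f"atp has {self.atp.shape[1]} dose columns but "
                f"{self.doses.size} doses given")
        if self.atp.shape[0] < 1:
            raise ValueError("need at least one replicate per dose")

    def mean_atp(self) -> np.ndarray:
        """Replicate-mean relative ATP per dose."""
        return self.atp.mean(axis=0)


def auc_trapezoid(curve: DoseResponseCurve, axis: str = "log10_dose") -> float:
    """Trapezoidal AUC of the replicate-mean curve over the chosen dose axis.

    Parameters
    ----------
    curve
        Validated dose-response curve.
    axis
        ``"log10_dose"`` (default) integrates against log10(dose);
        ``"linear_dose"`` against the raw dose grid.

    Returns
    -------
    float
        Area in (percent ATP) x (axis units); lower = more sensitive.
    """
    if axis == "log10_dose":
        x = np.log10(curve.doses)
    elif axis == "linear_dose":
        x = curve.doses
    else:
        raise ValueError(f"axis must be 'log10_dose' or 'linear_dose', got {axis!r}")
    return float(np.trapezoid(curve.mean_atp(), x))


def compare_measured(auc_by_sample: pd.Series, labels: pd.Series,
                     group: str = "GBM", control: str = "NPC",
                     mode: str = "auto") -> tuple[float, float]:
    """Two-group comparison of measured AUC: Wilcoxon p and HL location shift.

    Returns ``(p, hle)`` where ``hle`` is the Hodges-Lehmann estimate of the
    ``group`` minus ``control`` shift; negative means the GBM-like group is
    more sensitive.
    """
    from .nomination import hodges_lehmann, wilcoxon_rank_sum

    labels = labels.reindex(auc_by_sample.index)
    x = auc_by_sample[labels == group].to_numpy(dtype=float)
    y = auc_by_sample[labels == control].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError(f"both groups must be non-empty "
                         f"(|{group}|={x.size}, |{control}|={y.size})")
    return wilcoxon_rank_sum(x, y, mode=mode), hodges_lehmann(x, y)
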