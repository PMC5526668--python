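"""Efficiency-corrected ddCq copy-number quantification.

The copy number of the target locus in a sample, relative to a reference
locus and an ancestral calibrator, is

``N = (1 + E_t) ** (Cq_t,anc - Cq_t,sample) / (1 + E_r) ** (Cq_r,anc - Cq_r,sample)``

with per-assay efficiencies ``E`` as fractions (1.0 = perfect doubling). At
``E_t = E_r = 1`` this reduces to the classical ``2 ** -ddCq``; the calibrator
itself maps to ``N = 1`` by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .io import QpcrRecord

__all__ = ["CopyNumberEstimate", "copy_number_ddcq", "correlate_copy_cfp"]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    copy_number: float
    replicate_sd: float  # first-order (delta-method) propagation of Cq SDs


def copy_number_ddcq(sample: QpcrRecord, ancestor: QpcrRecord) -> CopyNumberEstimate:
    """Relative copy number of the target locus in ``sample`` vs. the
    ``ancestor`` calibrator, corrected for per-assay efficiency.

    Efficiencies are taken from ``sample`` and must match the calibrator's
    (same assays run on both). Replicate SD is propagated to the copy-number
    scale by the first-order delta method over the four Cq means.
    """
    e_t, e_r = sample.efficiency_target, sample.efficiency_reference
    if not math.isclose(e_t, ancestor.efficiency_target) or not math.isclose(
        e_r, ancestor.efficiency_reference
    ):
        raise ValueError("sample and calibrator must use the same assay efficiencies")
    dcq_t = ancestor.cq_target - sample.cq_target
    dcq_r = ancestor.cq_reference - sample.cq_reference
    n = (1.0 + e_t) ** dcq_t / (1.0 + e_r) ** dcq_r

    # var(log N) = ln(1+Et)^2 (var Cq_t,s + var Cq_t,anc) + likewise for ref
    lt, lr = math.log(1.0 + e_t), math.log(1.0 + e_r)

    def _sem2(sd: float, k: int) -> float:
        return (sd * sd / k) if k > 0 else 0.0

    var_log = lt * lt * (
        _sem2(sample.sd_target, sample.n_target)
        + _sem2(ancestor.sd_target, ancestor.n_target)
    ) + lr * lr * (
        _sem2(sample.sd_reference, sample.n_reference)
        + _sem2(ancestor.sd_reference, ancestor.n_reference)
    )
    return CopyNumberEstimate(
        sample_id=sample.sample_id,
        copy_number=float(n),
        replicate_sd=float(n * math.sqrt(var_log)),
    )


def correlate_copy_cfp(copies, cfp_final) -> tuple[float, float]:
    """Pearson correlation between qPCR copy numbers and final CFP
    fluorescence, with the two-sided t-based p-value."""
    if len(copies) != len(cfp_final):
        raise ValueError("paired vectors must have equal length")
    if len(copies) < 3:
        raise ValueError("need at least 3 paired values")
    res = stats.pearsonr(copies, cfp_final)
    return float(res.statistic), float(res.pvalue)
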