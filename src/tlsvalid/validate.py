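"""The validation battery: motion subsets, per-group verdicts, surveys.

A TLS group passes validation when the ADPs computed analytically from its
matrices agree (R_U at or below a threshold, default 0.05) with the ADPs
recovered from an explicitly sampled ensemble — for the full motion and for
each diagnostic subset of it.  The subsets isolate where a disagreement
comes from: all motions, librations without vibrations, each screw
libration alone, and each pure libration with its screw pitch removed.
Large screw pitches are the dominant failure mode; a pure libration that
passes while its screw variant fails points the finger directly.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decompose import (
    DecompositionResult,
    DecompositionStatus,
    SigmaStrategy,
    decompose,
)
from .ensemble import DEFAULT_MODELS, adp_from_ensemble, generate_ensemble
from .metrics import r_u
from .model import (
    AtomGroup,
    ElementalMotions,
    InvalidInputError,
    TLSMatrices,
    adp_from_motions,
)

__all__ = [
    "MotionSubset",
    "motion_subset",
    "SubsetResult",
    "ValidationReport",
    "Verdict",
    "validate_group",
    "survey",
    "DEFAULT_THRESHOLD",
    "REPORT_BANDS",
]

DEFAULT_THRESHOLD = 0.05
#: secondary reporting bands for survey histograms
REPORT_BANDS = (0.05, 0.10, 0.20)


class MotionSubset(enum.Enum):
    ALL = "all"
    NO_VIBRATION = "no_vibration"
    SCREW_X = "screw_x"
    SCREW_Y = "screw_y"
    SCREW_Z = "screw_z"
    PURE_LIBRATION_X = "pure_libration_x"
    PURE_LIBRATION_Y = "pure_libration_y"
    PURE_LIBRATION_Z = "pure_libration_z"

    @classmethod
    def coerce(cls, value) -> "MotionSubset":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise InvalidInputError(f"unknown motion subset: {value!r}") from None

    @property
    def axis(self) -> Optional[int]:
        name = self.value
        if name.endswith(("_x", "_y", "_z")):
            return "xyz".index(name[-1])
        return None


def motion_subset(m: ElementalMotions, spec) -> ElementalMotions:
    """Copy of ``m`` with the non-selected amplitudes zeroed.

    ``all`` is the identity; ``no_vibration`` zeroes t; ``screw_k`` keeps
    only libration k with its screw pitch and axis point; and
    ``pure_libration_k`` keeps libration k with the pitch removed.  Axes are
    never changed, so subset ADPs stay expressed in the same frames.
    """
    spec = MotionSubset.coerce(spec)
    out = m.copy()
    if spec is MotionSubset.ALL:
        return out
    out.t = np.zeros(3)
    if spec is MotionSubset.NO_VIBRATION:
        return out
    k = spec.axis
    keep_d = np.zeros(3)
    keep_d[k] = m.d[k]
    keep_s = np.zeros(3)
    if spec.value.startswith("screw"):
        keep_s[k] = m.s[k]
    out.d = keep_d
    out.s = keep_s
    return out


@dataclass
class SubsetResult:
    subset: MotionSubset
    r_u: float
    passed: bool


class Verdict(enum.Enum):
    COMPLIANT = "compliant"
    NON_COMPLIANT = "non_compliant"
    NOT_DECOMPOSABLE = "not_decomposable"
    LIBRATION_UNDEFINED = "libration_undefined"


@dataclass
class ValidationReport:
    """Per-group verdict plus the subset R_U table that produced it."""

    verdict: Verdict
    decomposition: DecompositionResult
    subsets: List[SubsetResult]
    strategy: SigmaStrategy
    threshold: float
    n_models: int
    seed: int
    annotations: List[str] = field(default_factory=list)

    def subset_r_u(self, spec) -> Optional[float]:
        spec = MotionSubset.coerce(spec)
        for s in self.subsets:
            if s.subset is spec:
                return s.r_u
        return None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "status": self.decomposition.status.value,
            "sigma": self.decomposition.sigma,
            "strategy": self.strategy.value,
            "threshold": self.threshold,
            "n_models": self.n_models,
            "seed": self.seed,
            "subsets": {s.subset.value: {"r_u": s.r_u, "pass": s.passed}
                        for s in self.subsets},
            "annotations": list(self.annotations),
            "warnings": list(self.decomposition.warnings),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_tsv(self) -> str:
        lines = ["subset\tr_u\tpass"]
        for s in self.subsets:
            lines.append(f"{s.subset.value}\t{s.r_u:.4f}\t{int(s.passed)}")
        return "\n".join(lines) + "\n"


def _subset_seed(root_seed: int, index: int) -> np.random.SeedSequence:
    # independent substream per subset: each subset result is reproducible
    # on its own, whatever other subsets run
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=(index,))


def validate_group(
    tls: TLSMatrices,
    group: AtomGroup,
    strategy=SigmaStrategy.S_MIN,
    n_models: int = DEFAULT_MODELS,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> ValidationReport:
    """Decompose, sample, compare — for the full motion and every subset.

    For each subset the analytic reference ADPs come from the *subset's own*
    motions (equivalently, its recomposed matrices), and the ensemble is
    drawn from an independent substream of the root seed.  Subsets whose
    libration amplitude is zero are skipped (there is nothing to sample).
    The verdict is ``compliant`` iff the decomposition succeeded and every
    computed subset passes the threshold.
    """
    strategy = SigmaStrategy.coerce(strategy)
    res = decompose(tls, strategy)
    if res.status not in (DecompositionStatus.OK,
                          DecompositionStatus.LIBRATION_UNDEFINED):
        return ValidationReport(
            Verdict.NOT_DECOMPOSABLE, res, [], strategy, threshold,
            n_models, seed)

    m = res.motions
    subsets: List[SubsetResult] = []
    annotations: List[str] = []
    for idx, spec in enumerate(MotionSubset):
        axis = spec.axis
        if axis is not None and m.d[axis] == 0.0:
            continue
        if spec is not MotionSubset.ALL and np.all(m.d == 0.0):
            continue  # nothing but vibrations: only the full motion is testable
        ms = motion_subset(m, spec)
        u_tls = adp_from_motions(ms, group)
        ens = generate_ensemble(ms, group, n_models, _subset_seed(seed, idx))
        u_ens = adp_from_ensemble(ens)
        value = r_u(u_tls, u_ens)
        subsets.append(SubsetResult(spec, value, value <= threshold))

    full = next((s for s in subsets if s.subset is MotionSubset.ALL), None)
    no_v = next((s for s in subsets if s.subset is MotionSubset.NO_VIBRATION), None)
    if full is not None and no_v is not None and no_v.r_u < full.r_u:
        annotations.append(
            "R_U(no_vibration) < R_U(all): vibrations, not librations, carry "
            "the disagreement for this group")

    if res.status is DecompositionStatus.LIBRATION_UNDEFINED:
        verdict = Verdict.LIBRATION_UNDEFINED
    elif all(s.passed for s in subsets):
        verdict = Verdict.COMPLIANT
    else:
        verdict = Verdict.NON_COMPLIANT
    return ValidationReport(verdict, res, subsets, strategy, threshold,
                            n_models, seed, annotations)


def _all_pass(report: ValidationReport, specs: Iterable[MotionSubset]) -> bool:
    vals = [report.subset_r_u(sp) for sp in specs]
    vals = [v for v in vals if v is not None]
    return bool(vals) and all(v <= report.threshold for v in vals)


def survey(
    groups: Sequence[Tuple[TLSMatrices, AtomGroup]],
    strategy=SigmaStrategy.S_MIN,
    n_models: int = DEFAULT_MODELS,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> Tuple[List[Optional[ValidationReport]], pd.DataFrame, dict]:
    """Batch-validate many groups and tally the category counts.

    Per-group failures are recorded, never fatal.  The summary counts
    partition the input: total = wrong content + all-zero + other
    non-decomposable + libration undefined + decomposed-ok; pass counts
    (overall motion, overall libration, individual screw, individual
    libration) are taken over the decomposed-ok groups.
    """
    strategy = SigmaStrategy.coerce(strategy)
    reports: List[Optional[ValidationReport]] = []
    rows = []
    counts = {
        "total": len(groups),
        "wrong_content": 0,
        "matrices_all_zero": 0,
        "not_decomposable_other": 0,
        "libration_undefined": 0,
        "decomposed": 0,
        "pass_overall_motion": 0,
        "pass_overall_libration": 0,
        "pass_individual_screw": 0,
        "pass_individual_libration": 0,
    }
    screw_specs = (MotionSubset.SCREW_X, MotionSubset.SCREW_Y, MotionSubset.SCREW_Z)
    pure_specs = (MotionSubset.PURE_LIBRATION_X, MotionSubset.PURE_LIBRATION_Y,
                  MotionSubset.PURE_LIBRATION_Z)
    for i, (tls, grp) in enumerate(groups):
        try:
            rep = validate_group(tls, grp, strategy, n_models,
                                 seed=int(np.random.SeedSequence(
                                     entropy=int(seed), spawn_key=(i,)
                                 ).generate_state(1)[0] % (2**31)),
                                 threshold=threshold)
        except Exception as exc:  # noqa: BLE001 — survey must never abort
            reports.append(None)
            counts["wrong_content"] += 1
            rows.append({"group": i, "verdict": "error", "error": str(exc)})
            continue
        reports.append(rep)
        status = rep.decomposition.status
        row = {"group": i, "verdict": rep.verdict.value,
               "status": status.value, "sigma": rep.decomposition.sigma}
        for spec in MotionSubset:
            val = rep.subset_r_u(spec)
            row[f"r_u_{spec.value}"] = val
        rows.append(row)
        if status is DecompositionStatus.WRONG_CONTENT:
            counts["wrong_content"] += 1
        elif status is DecompositionStatus.MATRICES_ALL_ZERO:
            counts["matrices_all_zero"] += 1
        elif status is DecompositionStatus.LIBRATION_UNDEFINED:
            counts["libration_undefined"] += 1
        elif status is not DecompositionStatus.OK:
            counts["not_decomposable_other"] += 1
        else:
            counts["decomposed"] += 1
            full = rep.subset_r_u(MotionSubset.ALL)
            no_v = rep.subset_r_u(MotionSubset.NO_VIBRATION)
            if full is not None and full <= threshold:
                counts["pass_overall_motion"] += 1
            if no_v is not None and no_v <= threshold:
                counts["pass_overall_libration"] += 1
            if _all_pass(rep, screw_specs):
                counts["pass_individual_screw"] += 1
            if _all_pass(rep, pure_specs):
                counts["pass_individual_libration"] += 1
    return reports, pd.DataFrame(rows), counts
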