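"""Synthetic case/control metabolomics datasets with known ground truth.

The generator emulates the statistical structure of a small two-group
metabolomics study of mouse spinal cord: 12 control vs 8 mutant samples,
289 detected metabolites of which 17 are so sparsely detected in one group
that the ≥50%-missing filter removes them, and 112 truly differential
metabolites (56 elevated, 56 decreased) whose effect sizes span the
fold-change range reported for such studies (0.27–1.14 case/control) with
within-group noise calibrated so that the designed effects are detectable
by a two-sample t-test at n = 12/8.

Abundances are multiplicative-lognormal: for feature *i* and sample *j*

    a_ij = base_i · r_i^[j is case] · 2^ε_ij / E[2^ε],   ε_ij ~ N(0, σ_i²)

with σ_i the within-group SD on the log2 scale.  Dividing by
E[2^ε] = exp((σ_i ln 2)² / 2) makes the arithmetic control-group mean equal
base_i, so the designed case/control ratio of arithmetic means is exactly
r_i — matching how fold change is computed downstream (on the raw scale,
before any normalization).

Missingness for the designated high-missing features is detection-limit
style: the ⌈rate · n_group⌉ lowest cells of the group are deleted
deterministically, so the realized missing proportion is ≥ the designed
rate by construction.  Any other nonzero rate is applied MCAR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq, elementwise

from .tables import FeatureTable, GROUP_CASE, GROUP_CONTROL

__all__ = [
    "StudyDesign",
    "MetaboliteSpec",
    "DesignError",
    "CalibrationError",
    "calibrate_noise",
    "default_specs",
    "generate_dataset",
    "ANCHOR_FEATURES",
]

#: Designed analogs of the three headline metabolites: (feature_id, fold
#: change case/control, target two-sided p-value at n = 12/8).
ANCHOR_FEATURES = (
    ("ascorbate_analog", 0.27, 2.4e-4),
    ("carnitine_analog", 0.71, 9.7e-10),
    ("glycine_analog", 1.14, 6.5e-4),
)


class DesignError(ValueError):
    """The study design violates its invariants."""


class CalibrationError(RuntimeError):
    """The requested p-value target cannot be reached at the given design."""


@dataclass(frozen=True)
class StudyDesign:
    """Counts defining the simulated study."""

    n_control: int = 12
    n_case: int = 8
    n_features: int = 289
    n_high_missing: int = 17
    n_up: int = 56
    n_down: int = 56
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_control, self.n_case, self.n_features)
        if any(c <= 0 for c in counts):
            raise DesignError("sample and feature counts must be positive")
        if min(self.n_high_missing, self.n_up, self.n_down) < 0:
            raise DesignError("feature-class counts must be nonnegative")
        if self.n_control + self.n_case < 4:
            raise DesignError("need at least 4 samples in total")
        if self.n_up + self.n_down > self.n_features - self.n_high_missing:
            raise DesignError(
                "n_up + n_down must not exceed n_features - n_high_missing"
            )

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_case

    @property
    def n_differential(self) -> int:
        return self.n_up + self.n_down


@dataclass(frozen=True)
class MetaboliteSpec:
    """Designed parameters of a single simulated metabolite."""

    feature_id: str
    base_level: float
    fold_change: float = 1.0
    noise_sd_log: float = 0.3
    missing_rate_control: float = 0.0
    missing_rate_case: float = 0.0
    #: delete the lowest cells (detection-limit censoring) instead of MCAR
    censor_lowest: bool = False

    def __post_init__(self) -> None:
        if self.base_level <= 0:
            raise DesignError(f"{self.feature_id}: base_level must be positive")
        if self.fold_change <= 0:
            raise DesignError(f"{self.feature_id}: fold_change must be positive")
        if self.noise_sd_log < 0:
            raise DesignError(f"{self.feature_id}: noise_sd_log must be >= 0")
        for rate in (self.missing_rate_control, self.missing_rate_case):
            if not 0.0 <= rate <= 1.0:
                raise DesignError(f"{self.feature_id}: missing rates must be in [0, 1]")

    @property
    def is_differential(self) -> bool:
        return self.fold_change != 1.0

    @property
    def is_high_missing(self) -> bool:
        return max(self.missing_rate_control, self.missing_rate_case) >= 0.5


def _welch_df_equal_sd(n1: int, n2: int) -> float:
    # Welch-Satterthwaite df when both groups share the same SD; the SD cancels.
    a, b = 1.0 / n1, 1.0 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def _two_sided_power(ncp, df: float, tcrit: float):
    """P(|T'| > tcrit) for a noncentral t with noncentrality ``ncp``.

    The lower-tail term underflows to NaN deep in the tail for large ncp;
    it is below machine precision there and is safely treated as zero.
    """
    lower = np.nan_to_num(stats.nct.cdf(-tcrit, df, ncp), nan=0.0)
    return stats.nct.sf(tcrit, df, ncp) + lower


def _solve_ncp(target_p: float, df: float) -> float:
    """Noncentrality at which the two-sided test has 50% power at level target_p."""
    tcrit = stats.t.isf(target_p / 2.0, df)
    f = lambda ncp: _two_sided_power(ncp, df, tcrit) - 0.5
    lo, hi = 1e-9, tcrit + 10.0
    if f(hi) < 0:  # pragma: no cover - extreme targets
        hi = tcrit + 50.0
    return brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)


@lru_cache(maxsize=4096)
def calibrate_noise(
    fold_change: float, n_control: int, n_case: int, target_p: float
) -> float:
    """Within-group log2 SD at which a designed effect 'typically' attains target_p.

    Solves the noncentral-t power relation
    ``P(two-sided p < target_p) = 0.5`` for the SD: the median p-value of a
    two-sample t-test on log2 data (equal group SDs, Welch df) then equals
    ``target_p``.  Monotone: a smaller target_p yields a smaller SD.

    Raises
    ------
    CalibrationError
        If ``target_p >= 0.5`` (the power of a two-sided level-α test never
        drops below α, so the relation has no solution) or fold_change is 1.
    """
    if not 0.0 < target_p < 1.0:
        raise CalibrationError("target_p must lie strictly between 0 and 1")
    if fold_change <= 0 or fold_change == 1.0:
        raise CalibrationError("fold_change must be positive and different from 1")
    if min(n_control, n_case) < 2:
        raise DesignError("need at least 2 samples per group")
    if target_p >= 0.5:
        raise CalibrationError(
            f"target_p={target_p} is unattainable: two-sided power never falls "
            "below the significance level, so no finite SD gives median p that large"
        )
    delta = abs(math.log2(fold_change))
    df = _welch_df_equal_sd(n_control, n_case)
    se_factor = math.sqrt(1.0 / n_control + 1.0 / n_case)
    ncp = _solve_ncp(target_p, df)
    return delta / (ncp * se_factor)


def _calibrate_noise_vec(fold_changes, target_ps, n_control: int, n_case: int):
    """Vectorized calibration used when building default spec lists."""
    fc = np.asarray(fold_changes, dtype=float)
    tp = np.asarray(target_ps, dtype=float)
    df = _welch_df_equal_sd(n_control, n_case)
    tcrit = stats.t.isf(tp / 2.0, df)

    def f(ncp, tcrit):
        return _two_sided_power(ncp, df, tcrit) - 0.5

    res = elementwise.find_root(
        f, (np.full_like(tcrit, 1e-9), tcrit + 10.0), args=(tcrit,)
    )
    delta = np.abs(np.log2(fc))
    se_factor = math.sqrt(1.0 / n_control + 1.0 / n_case)
    return delta / (res.x * se_factor)


def default_specs(design: StudyDesign) -> list[MetaboliteSpec]:
    """Build the default metabolite palette for a design.

    Layout: ``n_down`` decreased features (fold changes = reciprocals of
    values on [1.1, 4], anchored to include the 0.27 and 0.71 analogs),
    then ``n_up`` elevated features (fold changes on [1.1, 4], anchored to
    include the 1.14 analog), then null features, the last
    ``n_high_missing`` of which carry ≥50% detection-limit missingness in
    one or both groups.  Differential-feature noise SDs are calibrated so
    the designed effects have median p-values spanning 1e-10 … 1e-4 (the
    anchors use their quoted p-values).
    """
    rng = np.random.default_rng([design.seed, 0])
    n_null = design.n_features - design.n_differential

    down_anchors = [a for a in ANCHOR_FEATURES if a[1] < 1.0][: design.n_down]
    up_anchors = [a for a in ANCHOR_FEATURES if a[1] > 1.0][: design.n_up]

    def _sample_fc(n: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(1.1), math.log(4.0), size=n))

    def _sample_tp(n: int) -> np.ndarray:
        return 10.0 ** rng.uniform(-10.0, -4.0, size=n)

    ids: list[str] = []
    fcs: list[float] = []
    tps: list[float] = []
    # decreased block
    for fid, fc, tp in down_anchors:
        ids.append(fid)
        fcs.append(fc)
        tps.append(tp)
    n_rest = design.n_down - len(down_anchors)
    for fc, tp in zip(1.0 / _sample_fc(n_rest), _sample_tp(n_rest)):
        ids.append(f"met_down_{len(ids):03d}")
        fcs.append(float(fc))
        tps.append(float(tp))
    # elevated block
    for fid, fc, tp in up_anchors:
        ids.append(fid)
        fcs.append(fc)
        tps.append(tp)
    n_rest = design.n_up - len(up_anchors)
    for fc, tp in zip(_sample_fc(n_rest), _sample_tp(n_rest)):
        ids.append(f"met_up_{len(ids):03d}")
        fcs.append(float(fc))
        tps.append(float(tp))

    sds = _calibrate_noise_vec(fcs, tps, design.n_control, design.n_case)
    base = 10.0 ** rng.uniform(4.0, 7.0, size=design.n_features)

    specs = [
        MetaboliteSpec(
            feature_id=fid,
            base_level=float(base[i]),
            fold_change=float(fcs[i]),
            noise_sd_log=float(sds[i]),
        )
        for i, fid in enumerate(ids)
    ]

    null_sds = rng.uniform(0.2, 0.8, size=n_null)
    for j in range(n_null):
        i = design.n_differential + j
        high = j >= n_null - design.n_high_missing
        if high:
            # cycle through case-only / control-only / both-groups censoring
            which = (j - (n_null - design.n_high_missing)) % 3
            rate_c = 0.5 if which in (1, 2) else 0.0
            rate_m = 0.5 if which in (0, 2) else 0.0
            fid = f"met_sparse_{i:03d}"
        else:
            rate_c = rate_m = 0.0
            fid = f"met_null_{i:03d}"
        specs.append(
            MetaboliteSpec(
                feature_id=fid,
                base_level=float(base[i]),
                noise_sd_log=float(null_sds[j]),
                missing_rate_control=rate_c,
                missing_rate_case=rate_m,
                censor_lowest=high,
            )
        )
    return specs


def _generate_metadata(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    sample_ids = [f"ctl_{i + 1:02d}" for i in range(design.n_control)] + [
        f"mut_{i + 1:02d}" for i in range(design.n_case)
    ]
    groups = [GROUP_CONTROL] * design.n_control + [GROUP_CASE] * design.n_case
    n = design.n_samples
    n_litters = max(2, round(n / 4))
    litters = rng.integers(0, n_litters, size=n)
    litter_dob = {
        k: date(2015, 3, 1) + timedelta(days=int(d))
        for k, d in enumerate(rng.integers(0, 60, size=n_litters))
    }
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "sex": rng.choice(["F", "M"], size=n),
            "litter": [f"litter_{k + 1}" for k in litters],
            "date_of_birth": [litter_dob[int(k)].isoformat() for k in litters],
        }
    )


def generate_dataset(
    design: StudyDesign, specs: list[MetaboliteSpec] | None = None
) -> tuple[FeatureTable, pd.DataFrame, pd.DataFrame]:
    """Simulate a raw feature table, sample metadata, and the truth table.

    Same (design, specs) ⇒ bit-identical output.  The truth table records
    every designed parameter plus ``is_differential`` / ``is_high_missing``
    flags.
    """
    if specs is None:
        specs = default_specs(design)
    if len(specs) != design.n_features:
        raise DesignError(
            f"got {len(specs)} specs for a design with {design.n_features} features"
        )
    seen = {s.feature_id for s in specs}
    if len(seen) != len(specs):
        raise DesignError("duplicate feature_id in specs")
    n_high = sum(s.is_high_missing for s in specs)
    if n_high != design.n_high_missing:
        raise DesignError(
            f"specs designate {n_high} high-missing features, design says "
            f"{design.n_high_missing}"
        )

    rng = np.random.default_rng([design.seed, 1])
    metadata = _generate_metadata(design, np.random.default_rng([design.seed, 2]))
    is_case = (metadata["group"] == GROUP_CASE).to_numpy()
    n = design.n_samples

    values = np.empty((n, design.n_features))
    for j, spec in enumerate(specs):
        eps = rng.normal(0.0, spec.noise_sd_log, size=n)
        correction = math.exp((spec.noise_sd_log * math.log(2)) ** 2 / 2.0)
        col = spec.base_level * np.exp2(eps) / correction
        col[is_case] *= spec.fold_change
        values[:, j] = col

    # missingness second, in a fixed order, so the value draws above are
    # unaffected by the rates
    for j, spec in enumerate(specs):
        for mask, rate in (
            (~is_case, spec.missing_rate_control),
            (is_case, spec.missing_rate_case),
        ):
            if rate <= 0:
                continue
            idx = np.flatnonzero(mask)
            if spec.censor_lowest:
                m = math.ceil(rate * idx.size)
                drop = idx[np.argsort(values[idx, j], kind="stable")[:m]]
            else:
                drop = idx[rng.random(idx.size) < rate]
            values[drop, j] = np.nan

    table = FeatureTable(
        pd.DataFrame(
            values,
            index=pd.Index(metadata["sample_id"], name="sample_id"),
            columns=[s.feature_id for s in specs],
        )
    )
    truth = pd.DataFrame(
        [
            {
                "feature_id": s.feature_id,
                "base_level": s.base_level,
                "fold_change": s.fold_change,
                "noise_sd_log": s.noise_sd_log,
                "missing_rate_control": s.missing_rate_control,
                "missing_rate_case": s.missing_rate_case,
                "is_differential": s.is_differential,
                "is_high_missing": s.is_high_missing,
            }
            for s in specs
        ]
    )
    return table, metadata, truth
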