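"""Allometric and geometric scaling between individuals and breeds.

Limb muscle mass and total physiological cross-sectional area (PCSA) scale
with body mass following power laws; fitting a least-squares line in
log-log space gives the allometric exponent used to transfer per-muscle
PCSA (and with it maximum isometric force) from a source individual to a
target body mass.  Muscle mass itself is scaled linearly with the
body-mass ratio; length-type parameters (fibre length, tendon slack) are
left untouched here because they follow the geometric scale factors
applied to the skeleton.

Geometry scales with one factor per limb and one for the axial skeleton
(spine, neck, head); segment length fractions are nearly breed-invariant,
so a single limb factor suffices.  The packaged presets carry the
published 1.66 (limb) / 1.25 (axial) factor pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import ModelConfig, Muscle, MuscleParams, MusclePath, WrapObstacle

__all__ = [
    "AllometricFit",
    "SCALE_PRESETS",
    "fit_loglog",
    "scale_muscle_params",
    "scale_geometry",
    "read_morphometry_csv",
    "write_morphometry_csv",
]

#: Specific tension used to derive fmax from PCSA when absent (N/m²).
SPECIFIC_TENSION = 3.0e5

MORPHOMETRY_COLUMNS = ["name", "m", "ml", "fl", "alpha_deg", "pcsa", "fmax"]

#: Named geometric presets (limb_factor, axial_factor).  "beagle_to_gs"
#: carries the published factors that map the smaller breed's skeleton onto
#: the German-Shepherd-sized muscle model; "gs_to_beagle" is its inverse.
SCALE_PRESETS = {
    "beagle_to_gs": (1.66, 1.25),
    "gs_to_beagle": (1.0 / 1.66, 1.0 / 1.25),
}


@dataclass(frozen=True)
class AllometricFit:
    """Least-squares line in log-log space: log(y) = slope*log(M) + intercept."""

    slope: float
    intercept: float
    residuals: np.ndarray
    n: int
    slope_se: float

    def predict(self, body_mass: float) -> float:
        return float(np.exp(self.intercept) * body_mass**self.slope)


def fit_loglog(body_mass, totals) -> AllometricFit:
    """Fit ``log(total) = slope * log(body_mass) + intercept``.

    ``totals`` is any per-limb aggregate (total muscle mass, total PCSA).
    All values must be positive; at least two points are required.
    """
    M = np.asarray(body_mass, dtype=float)
    y = np.asarray(totals, dtype=float)
    if M.size != y.size or M.size < 2:
        raise ValueError("need matching arrays with at least 2 points")
    if np.any(M <= 0) or np.any(y <= 0):
        raise ValueError("body mass and totals must be > 0 for a log-log fit")
    x = np.log(M)
    ly = np.log(y)
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, ly, rcond=None)
    resid = ly - (slope * x + intercept)
    if M.size > 2:
        s2 = float(resid @ resid) / (M.size - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = np.sqrt(s2 / sxx) if sxx > 0 else np.inf
    else:
        se = 0.0
    return AllometricFit(
        slope=float(slope), intercept=float(intercept), residuals=resid,
        n=int(M.size), slope_se=float(se),
    )


def scale_muscle_params(
    params: MuscleParams,
    fit: AllometricFit,
    target_mass: float,
    source_mass: float,
) -> MuscleParams:
    """Transfer muscle parameters to a new body mass.

    PCSA (and fmax with it) is multiplied by the fitted allometric ratio
    ``ŷ(target)/ŷ(source)``; muscle mass scales linearly with the body-mass
    ratio; length parameters are untouched (they ride on the geometric
    scaling of the skeleton).
    """
    if fit is None:
        raise ValueError("an AllometricFit is required to scale PCSA")
    if target_mass <= 0 or source_mass <= 0:
        raise ValueError("body masses must be > 0")
    ratio = fit.predict(target_mass) / fit.predict(source_mass)
    return replace(
        params,
        pcsa=params.pcsa * ratio,
        fmax=params.fmax * ratio,
        m=params.m * (target_mass / source_mass),
    )


def scale_geometry(
    model: ModelConfig,
    limb_factor: float,
    axial_factor: float = 1.0,
    limb_segments: set[str] | None = None,
) -> ModelConfig:
    """Scale model geometry: limb segments by one factor, axial by another.

    Joint offsets, muscle attachment points, segment COM positions, and
    wrap radii/centres are multiplied by the factor of the segment they
    live on (a joint offset is geometry of its parent segment).  Masses
    and inertia tensors are deliberately left for explicit rescaling by
    the caller — geometric similarity does not fix them.
    """
    if limb_factor <= 0 or axial_factor <= 0:
        raise ValueError("scale factors must be > 0")

    def factor(seg: str) -> float:
        if limb_segments is None:
            return limb_factor
        return limb_factor if seg in limb_segments else axial_factor

    segments = {
        name: replace(s, com=s.com * factor(name))
        for name, s in model.segments.items()
    }
    joints = [
        replace(j, frame_translation=j.frame_translation * factor(j.parent))
        for j in model.joints
    ]
    wraps = {
        name: WrapObstacle(
            name=w.name, kind=w.kind, segment=w.segment,
            centre=w.centre * factor(w.segment), radius=w.radius * factor(w.segment),
            axis=w.axis,
        )
        for name, w in model.wraps.items()
    }
    muscles = [
        Muscle(
            path=MusclePath(
                name=m.path.name,
                points=tuple((seg, p * factor(seg)) for seg, p in m.path.points),
                wraps=m.path.wraps,
            ),
            params=m.params,
        )
        for m in model.muscles
    ]
    return ModelConfig(
        segments=segments, joints=joints, muscles=muscles, wraps=wraps,
        gravity=model.gravity.copy(), ground=model.ground,
    )


def read_morphometry_csv(path) -> pd.DataFrame:
    """Read a muscle morphometry table (name,m,ml,fl,alpha_deg,pcsa,fmax).

    ``fmax`` may be empty; it is then derived from PCSA via the specific
    tension constant.
    """
    df = pd.read_csv(path)
    missing = [c for c in MORPHOMETRY_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"morphometry table missing columns {missing}")
    if "fmax" not in df.columns:
        df["fmax"] = np.nan
    df["fmax"] = df["fmax"].fillna(df["pcsa"] * SPECIFIC_TENSION)
    return df[MORPHOMETRY_COLUMNS]


def write_morphometry_csv(df: pd.DataFrame, path) -> None:
    df[MORPHOMETRY_COLUMNS].to_csv(path, index=False)
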