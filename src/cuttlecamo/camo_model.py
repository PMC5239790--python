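"""Behavioral camouflage model for a swimming cuttlefish.

The model formalizes intensity matching during movement as a small state
machine evaluated at every step of a crossing:

1. **PSE** (Patch Size Estimation): the animal assesses the width of any
   upcoming high-contrast substrate patch.  Here PSE is perfect-knowledge,
   read from the arena geometry within a forward lookahead window.
2. **CEPS gate**: if an identified patch is narrower than the Camouflage
   Eliciting Patch Size threshold (by default the animal's own mantle
   length), it is ignored — no reflectance change is elicited.
3. **CSA averaging**: otherwise the animal averages the background
   reflectance over its Camouflage Sampling Area, a forward-skewed oval
   subregion of the visual field (4530 px for the packaged default
   geometry), optionally minus an occluded dead zone under the body.
4. **Delta gate**: if the mismatch between Self Reflectance (SR, the
   current mantle reflectance) and the CSA mean is below a threshold, the
   animal is already cryptic and does nothing.
5. **Update**: otherwise SR moves toward the (noise-perturbed) CSA mean by
   a fraction ``gain`` of the gap.

A patch counts as "identified" while any part of it is still within the
animal's visual surroundings (forward lookahead plus the rear extent of
the CSA); once it is fully behind the visual field the CSA is uniform
again and the delta gate takes over.  This makes sub-threshold patches
elicit *exactly* no response while still letting the animal brighten back
up when leaving a large patch.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .arena import ArenaSpec, ReflectanceField

__all__ = [
    "CSAGeometry",
    "CSAMask",
    "ModelParams",
    "ModelState",
    "Decision",
    "ReflectanceTrace",
    "ConfigurationError",
    "DEFAULT_CSA_GEOMETRY",
    "make_csa_mask",
    "csa_mean",
    "estimate_patch_size",
    "camo_decision",
    "simulate_crossing",
    "model_overlay",
]


class ConfigurationError(ValueError):
    """Raised when a geometry/parameter set violates its packaged contract."""


# --------------------------------------------------------------------------
# sampling-area geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CSAGeometry:
    """Parameters of the Camouflage Sampling Area oval.

    The oval's across-tank center sits on a pixel *corner* (row offsets are
    half-integers): an oval centered on a pixel center always contains an
    odd number of pixels, so the packaged 4530-px area would be
    unreachable.  ``forward_skew_px`` shifts the oval center ahead of the
    animal along the movement direction, implementing anticipation.  The
    dead zone is an occluded oval under the body, centered on the animal.
    """

    semi_axis_along_px: float = 39.5
    semi_axis_across_px: float = 36.5115
    forward_skew_px: int = 20
    deadzone_semi_axis_along_px: float = 0.0
    deadzone_semi_axis_across_px: float = 0.0
    target_area_px: int | None = 4530

    def __post_init__(self) -> None:
        if self.semi_axis_along_px <= 0 or self.semi_axis_across_px <= 0:
            raise ValueError("semi-axes must be positive")
        if self.forward_skew_px < 0:
            raise ValueError("forward_skew_px must be non-negative")

    @property
    def has_deadzone(self) -> bool:
        return (
            self.deadzone_semi_axis_along_px > 0
            and self.deadzone_semi_axis_across_px > 0
        )

    def to_dict(self) -> dict:
        return {
            "semi_axis_along_px": self.semi_axis_along_px,
            "semi_axis_across_px": self.semi_axis_across_px,
            "forward_skew_px": self.forward_skew_px,
            "deadzone_semi_axis_along_px": self.deadzone_semi_axis_along_px,
            "deadzone_semi_axis_across_px": self.deadzone_semi_axis_across_px,
            "target_area_px": self.target_area_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CSAGeometry":
        return cls(**d)


#: packaged default geometry; rasterizes to exactly 4530 pixels
DEFAULT_CSA_GEOMETRY = CSAGeometry()


@dataclass(frozen=True)
class CSAMask:
    """Rasterized CSA mask plus its placement relative to the animal.

    ``mask[j, k]`` covers the field pixel
    ``(animal_row + row0 + j, animal_col + col0 + k)``.  ``col0`` already
    includes the forward skew.  ``column_counts[k]`` is the number of true
    pixels in mask column ``k`` (used by the fast 1-D simulation path,
    valid whenever the mask is not clipped across the tank).
    """

    mask: np.ndarray = field(repr=False)
    row0: int
    col0: int
    forward_skew_px: int

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def column_counts(self) -> np.ndarray:
        return self.mask.sum(axis=0)

    @property
    def along_extent_px(self) -> int:
        """Number of pixel columns spanned by the oval."""
        return self.mask.shape[1]

    @property
    def rear_extent_px(self) -> int:
        """How far the mask reaches behind the animal position (pixels)."""
        return max(0, -self.col0)


def make_csa_mask(geometry: CSAGeometry = DEFAULT_CSA_GEOMETRY) -> CSAMask:
    """Rasterize a :class:`CSAGeometry` into a :class:`CSAMask`.

    Pixel membership is tested on pixel centers:
    ``(dx/a)**2 + (dy/b)**2 <= 1`` with integer column offsets ``dx`` and
    half-integer row offsets ``dy`` (corner-centered across the tank).
    Dead-zone pixels (same test against the dead-zone oval, centered on
    the animal, i.e. offset ``-forward_skew_px`` columns from the oval
    center) are removed.

    Raises :class:`ConfigurationError` if ``target_area_px`` is set and
    the rasterized count differs from it.
    """
    a, b = geometry.semi_axis_along_px, geometry.semi_axis_across_px
    fa = int(math.floor(a))
    nrow_half = int(math.floor(b + 0.5))  # dy = 0.5 .. nrow_half - 0.5
    dx = np.arange(-fa, fa + 1, dtype=float)
    dy = np.arange(-nrow_half, nrow_half, dtype=float) + 0.5
    DX, DY = np.meshgrid(dx, dy)
    mask = (DX / a) ** 2 + (DY / b) ** 2 <= 1.0
    if geometry.has_deadzone:
        da = geometry.deadzone_semi_axis_along_px
        db = geometry.deadzone_semi_axis_across_px
        dead = ((DX + geometry.forward_skew_px) / da) ** 2 + (DY / db) ** 2 <= 1.0
        mask &= ~dead
    out = CSAMask(
        mask=mask,
        row0=-nrow_half + 1,
        col0=geometry.forward_skew_px - fa,
        forward_skew_px=geometry.forward_skew_px,
    )
    if geometry.target_area_px is not None and out.area_px != geometry.target_area_px:
        raise ConfigurationError(
            f"CSA geometry rasterizes to {out.area_px} px, expected "
            f"{geometry.target_area_px}"
        )
    return out


def csa_mean(
    fld: ReflectanceField, csamask: CSAMask, animal_rc: tuple[int, int]
) -> float:
    """Mean background reflectance over the CSA placed at the animal.

    ``animal_rc`` is the animal's (row, column) position in field pixels.
    Mask pixels falling outside the field are dropped from the average
    (edge clipping); if every pixel falls outside, raise ``ValueError``.
    """
    r, c = animal_rc
    m = csamask.mask
    rows = r + csamask.row0 + np.arange(m.shape[0])
    cols = c + csamask.col0 + np.arange(m.shape[1])
    rin = (rows >= 0) & (rows < fld.n_rows)
    cin = (cols >= 0) & (cols < fld.n_cols)
    sub = m[np.ix_(rin, cin)]
    n = int(sub.sum())
    if n == 0:
        raise ValueError("CSA mask lies entirely outside the field")
    vals = fld.values[np.ix_(rows[rin], cols[cin])]
    return float(vals[sub].sum() / n)


# --------------------------------------------------------------------------
# patch-size estimation and the decision rule
# --------------------------------------------------------------------------

def estimate_patch_size(
    spec: ArenaSpec,
    position_cm: float,
    lookahead_cm: float = 30.0,
    rear_margin_cm: float = 0.0,
) -> float | None:
    """Perfect-knowledge PSE: width of the black band if any part of it
    lies within ``[position - rear_margin, position + lookahead]``, else
    ``None``.  A patch fully behind the window returns ``None`` (with the
    default zero rear margin: fully behind the animal).
    """
    if not 0.0 <= position_cm <= spec.length_cm:
        raise ValueError("position outside tank")
    if spec.patch_width_cm <= 0:
        return None
    left, right = spec.patch_interval_cm
    if left < position_cm + lookahead_cm and right > position_cm - rear_margin_cm:
        return spec.patch_width_cm
    return None


class Decision(enum.IntEnum):
    UPDATE = 0
    NO_CHANGE_MATCHED = 1
    NO_CHANGE_SMALL_PATCH = 2


@dataclass(frozen=True)
class ModelParams:
    """Tunable model parameters.

    ``ceps_threshold_cm`` — CEPS gate; by convention the animal's mantle
    length.  A patch exactly equal to the threshold opens the gate
    (inclusive ``>=``).
    ``delta_threshold_pct`` — dead band on ``|SR - CSA|`` below which the
    animal considers itself matched.
    ``gain`` — fraction of the SR-to-CSA gap closed per step; 1 is the
    instantaneous matching of the original conceptual model, the data
    generator calibrates smaller per-crossing values.
    ``noise_halfrange_pct`` — half-range of the uniform stochastic
    behavior factor applied to the *perceived* CSA mean on update steps
    (at gain 1 this is additive noise on SR itself).
    ``baseline_noise_halfrange_pct`` — half-range of the uniform
    per-step wander applied on no-change steps (0 for pure model runs).
    """

    ceps_threshold_cm: float = 10.2
    delta_threshold_pct: float = 0.5
    gain: float = 1.0
    noise_halfrange_pct: float = 3.0
    baseline_noise_halfrange_pct: float = 0.0
    step_px: int = 1
    lookahead_cm: float = 30.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gain <= 1.0:
            raise ValueError("gain must be in [0, 1]")
        if self.delta_threshold_pct < 0 or self.noise_halfrange_pct < 0:
            raise ValueError("thresholds must be non-negative")
        if self.baseline_noise_halfrange_pct < 0:
            raise ValueError("baseline noise must be non-negative")
        if self.step_px < 1:
            raise ValueError("step_px must be a positive integer")
        if self.ceps_threshold_cm <= 0 or self.lookahead_cm <= 0:
            raise ValueError("ceps threshold and lookahead must be positive")

    def to_dict(self) -> dict:
        return {
            "ceps_threshold_cm": self.ceps_threshold_cm,
            "delta_threshold_pct": self.delta_threshold_pct,
            "gain": self.gain,
            "noise_halfrange_pct": self.noise_halfrange_pct,
            "baseline_noise_halfrange_pct": self.baseline_noise_halfrange_pct,
            "step_px": self.step_px,
            "lookahead_cm": self.lookahead_cm,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass
class ModelState:
    """Instantaneous model state during a crossing."""

    position_cm: float
    sr_pct: float
    responding: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.sr_pct <= 100.0:
            raise ValueError("sr_pct must be in [0, 100]")


def camo_decision(
    state: ModelState, params: ModelParams, pse: float | None, csa: float
) -> Decision:
    """One evaluation of the decision rule.

    An identified patch narrower than the CEPS threshold blocks any
    response.  Otherwise — including when no patch is identified at all —
    the animal compares SR to the CSA mean and updates when the mismatch
    exceeds the delta threshold.
    """
    if pse is not None and pse < params.ceps_threshold_cm:
        return Decision.NO_CHANGE_SMALL_PATCH
    if abs(state.sr_pct - csa) <= params.delta_threshold_pct:
        return Decision.NO_CHANGE_MATCHED
    return Decision.UPDATE


# --------------------------------------------------------------------------
# crossing simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReflectanceTrace:
    """Positionally indexed SR trace of one simulated crossing.

    ``x_cm`` is the along-travel coordinate re-centered so 0 marks the
    gray-to-black boundary first encountered (tank center for control
    arenas).  ``s_cm`` is the raw marching distance from the start.
    """

    s_cm: np.ndarray = field(repr=False)
    x_cm: np.ndarray = field(repr=False)
    sr_pct: np.ndarray = field(repr=False)
    decisions: np.ndarray = field(repr=False)
    direction: str = "forward"

    def __len__(self) -> int:
        return len(self.sr_pct)


def _csa_column_profile(colvals: np.ndarray, csamask: CSAMask) -> np.ndarray:
    """CSA mean for every animal column position, mask not clipped in rows.

    The tank field is constant down each column, so the CSA mean reduces
    to a weighted average of column values with the mask's per-column
    pixel counts as weights.  Out-of-field columns are edge-clipped
    (dropped from the average).
    """
    cc = csamask.column_counts.astype(float)
    K = len(cc)
    half = K // 2  # kernel is odd: columns -fa .. fa
    skew = csamask.forward_skew_px
    n = len(colvals)
    pad = half + skew
    vp = np.concatenate([np.zeros(pad), colvals.astype(float), np.zeros(pad)])
    mp = np.concatenate([np.zeros(pad), np.ones(n), np.zeros(pad)])
    # out[i] = sum_dx cc[dx] * v[j + dx] for oval center j = i - skew
    num = np.convolve(vp, cc[::-1], mode="valid")
    den = np.convolve(mp, cc[::-1], mode="valid")
    # animal position p -> oval center j = p + skew -> index i = p + 2*skew
    i = np.arange(n) + 2 * skew
    prof = np.full(n, np.nan)
    ok = den[i] > 0
    prof[ok] = num[i][ok] / den[i][ok]
    return prof


def simulate_crossing(
    fld: ReflectanceField,
    spec: ArenaSpec,
    params: ModelParams,
    start_sr: float | None = None,
    direction: str = "forward",
    rng: np.random.Generator | None = None,
    csamask: CSAMask | None = None,
) -> ReflectanceTrace:
    """Step an animal across the full arena and return its SR trace.

    The animal marches ``step_px`` pixels at a time from one tank end to
    the other along the mid-line.  At each step the PSE/CEPS/delta rule is
    evaluated; on UPDATE, ``sr += gain * ((csa + eta) - sr)`` with
    ``eta ~ U(-noise_halfrange, +noise_halfrange)``; on NO_CHANGE,
    ``sr += eta'`` with ``eta' ~ U(-baseline, +baseline)``.  SR is clipped
    to [0, 100].
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if start_sr is None:
        start_sr = spec.gray_reflectance
    if not 0.0 <= start_sr <= 100.0:
        raise ValueError("start_sr must be in [0, 100]")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if csamask is None:
        csamask = make_csa_mask()
    if csamask.mask.shape[0] > fld.n_rows:
        raise ValueError("field too narrow across the tank for the CSA mask")

    ppc = fld.px_per_cm
    colvals = fld.column_values()
    if direction == "reverse":
        colvals = colvals[::-1]

    csa_prof = _csa_column_profile(colvals, csamask)
    n_cols = len(colvals)
    positions = np.arange(0, n_cols, params.step_px)
    s_cm = positions / ppc

    # patch edges in the marching frame
    if spec.patch_width_cm > 0:
        left, right = spec.patch_interval_cm
        if direction == "reverse":
            left, right = spec.length_cm - right, spec.length_cm - left
        s0 = left
    else:
        left = right = None
        s0 = spec.length_cm / 2.0

    # a patch is "identified" while any part of it is within
    # [s - rear_extent, s + lookahead]; rear extent = CSA reach behind body
    rear_cm = csamask.rear_extent_px / ppc
    if left is not None:
        identified = (left < s_cm + params.lookahead_cm) & (s_cm - rear_cm < right)
        blocked = identified & (spec.patch_width_cm < params.ceps_threshold_cm)
    else:
        blocked = np.zeros(len(positions), dtype=bool)

    csa_steps = csa_prof[positions]
    if np.isnan(csa_steps).any():
        raise ValueError("CSA mask entirely outside the field at some step")

    noise_free = (
        params.noise_halfrange_pct == 0.0
        and params.baseline_noise_halfrange_pct == 0.0
    )
    if noise_free and params.delta_threshold_pct == 0.0 and not blocked.any():
        sr = _filter_path(csa_steps, params.gain, start_sr)
        dec = np.full(len(positions), Decision.UPDATE, dtype=np.int8)
        dec[np.isclose(sr, csa_steps)] = Decision.NO_CHANGE_MATCHED
    else:
        sr, dec = _loop_path(csa_steps, blocked, params, start_sr, rng, noise_free)

    return ReflectanceTrace(
        s_cm=s_cm,
        x_cm=s_cm - s0,
        sr_pct=sr,
        decisions=dec,
        direction=direction,
    )


def _filter_path(csa: np.ndarray, gain: float, start_sr: float) -> np.ndarray:
    """Exact vectorized form of the noise-free, zero-delta update recurrence
    ``sr[n] = (1 - g) sr[n-1] + g csa[n]`` via a first-order IIR filter."""
    if gain == 0.0:
        return np.full(len(csa), start_sr)
    b, a = [gain], [1.0, -(1.0 - gain)]
    zi = np.array([(1.0 - gain) * start_sr])
    sr, _ = lfilter(b, a, csa, zi=zi)
    return np.clip(sr, 0.0, 100.0)


def _loop_path(
    csa: np.ndarray,
    blocked: np.ndarray,
    params: ModelParams,
    start_sr: float,
    rng: np.random.Generator,
    noise_free: bool,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(csa)
    if noise_free:
        eta = eta_b = np.zeros(n)
    else:
        eta = (
            rng.uniform(-params.noise_halfrange_pct, params.noise_halfrange_pct, n)
            if params.noise_halfrange_pct > 0
            else np.zeros(n)
        )
        eta_b = (
            rng.uniform(
                -params.baseline_noise_halfrange_pct,
                params.baseline_noise_halfrange_pct,
                n,
            )
            if params.baseline_noise_halfrange_pct > 0
            else np.zeros(n)
        )
    sr = np.empty(n)
    dec = np.empty(n, dtype=np.int8)
    s = start_sr
    g = params.gain
    delta = params.delta_threshold_pct
    csa_l = csa.tolist()
    blocked_l = blocked.tolist()
    eta_l = eta.tolist()
    eta_b_l = eta_b.tolist()
    for i in range(n):
        if blocked_l[i]:
            s += eta_b_l[i]
            d = Decision.NO_CHANGE_SMALL_PATCH
        else:
            perceived = csa_l[i] + eta_l[i]
            if abs(s - perceived) <= delta:
                s += eta_b_l[i]
                d = Decision.NO_CHANGE_MATCHED
            else:
                s += g * (perceived - s)
                d = Decision.UPDATE
        if s < 0.0:
            s = 0.0
        elif s > 100.0:
            s = 100.0
        sr[i] = s
        dec[i] = d
    return sr, dec


def model_overlay(
    traces: list[ReflectanceTrace], grid_cm: np.ndarray | None = None
):
    """Align traces onto a common uniform position grid by linear
    interpolation; returns a DataFrame with ``x_cm`` plus one column per
    trace, suitable for superimposing model runs over measured data."""
    import pandas as pd

    if not traces:
        raise ValueError("no traces given")
    if grid_cm is None:
        lo = max(t.x_cm.min() for t in traces)
        hi = min(t.x_cm.max() for t in traces)
        step = float(np.median(np.diff(traces[0].x_cm)))
        grid_cm = np.arange(lo, hi + step / 2, step)
    out = {"x_cm": grid_cm}
    for k, t in enumerate(traces):
        out[f"trace_{k}"] = np.interp(grid_cm, t.x_cm, t.sr_pct)
    return pd.DataFrame(out)
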