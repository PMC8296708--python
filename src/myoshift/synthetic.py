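"""Synthetic study-data generators.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the downstream methods assume: right-skewed
(lognormal) fiber-CSA distributions with an additive or multiplicative
treatment effect, one-compartment oral PK curves, Sirius-Red-like histology
fixtures with an exact red-pixel fraction, grip-force trajectories with
5 trials per session, and treadmill exhaustion times with shock caps.  The
generators emulate the statistical *shapes* only — no degeneration /
regeneration biology is modelled.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .csa_shift import CSASample
from .histopathology import (
    LESION_PARAMETERS,
    FiberAnnotation,
    SeverityCard,
    SeverityFinding,
)
from .pharmacokinetics import ConcSeries

__all__ = [
    "FIBROSIS_RED",
    "BACKGROUND_RGB",
    "CSAGenConfig",
    "PKGenConfig",
    "FunctionalGenConfig",
    "InvalidEffectError",
    "DegenerateModelError",
    "gen_csa_samples",
    "gen_pk_profile",
    "one_compartment_conc",
    "gen_histology_image",
    "gen_grip_study",
    "gen_treadmill_study",
    "gen_severity_cards",
    "gen_fiber_annotations",
    "write_fiber_table",
    "read_fiber_table",
    "write_pk_table",
    "read_pk_table",
    "save_histology_png",
]

#: Exact RGB triplet used for fibrosis-red pixels in generated fixtures.
#: Chosen to sit well inside the default red HSV window (hue ~0.98,
#: saturation ~0.81) so fixture arithmetic is bit-exact.
FIBROSIS_RED = (178, 34, 52)
#: Pale eosin-like background; saturation ~0.06, below the red classifier's
#: minimum saturation.
BACKGROUND_RGB = (235, 220, 225)

#: PK sampling grid (hours post dose) used in the tissue-exposure study.
PK_SAMPLING_TIMES_H = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0)
#: Oral doses (mg/kg) of the single-dose PK study.
PK_DOSES_MG_PER_KG = (5.0, 10.0, 25.0, 37.5)


class InvalidEffectError(ValueError):
    """Configured effect would produce non-positive fiber areas."""


class DegenerateModelError(ValueError):
    """ka = ke: the one-compartment oral solution is singular."""


# ---------------------------------------------------------------------------
# fiber CSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSAGenConfig:
    """Ground-truth configuration for a control/treated fiber-CSA pair.

    Fiber areas are lognormal: area = median_um2 * exp(sigma_log * Z).
    ``effect_kind`` applies the treatment to an independent (default) or
    paired re-draw of the control law: additive adds S = effect_value um^2,
    multiplicative scales by K = effect_value; 5% multiplicative
    measurement noise corresponds to noise_frac = 0.05.  ``mouse_sd_log``
    adds an optional between-mouse lognormal random effect on top of the
    within-mouse variation (defaults to 0: all variance within mouse).
    """

    n_fibers: int = 500
    median_um2: float = 500.0
    sigma_log: float = 0.5
    effect_kind: str = "none"
    effect_value: float = 0.0
    noise_frac: float = 0.0
    seed: int = 0
    paired: bool = False
    n_mice: int = 5
    mouse_sd_log: float = 0.0
    muscle: str = "GAS"

    def __post_init__(self) -> None:
        if self.n_fibers < 10:
            raise ValueError("n_fibers must be >= 10")
        if self.median_um2 <= 0 or self.sigma_log <= 0:
            raise ValueError("median_um2 and sigma_log must be positive")
        if self.effect_kind not in ("none", "additive", "multiplicative"):
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if self.effect_kind == "multiplicative" and self.effect_value <= 0:
            raise ValueError("multiplicative factor K must be positive")
        if self.noise_frac < 0 or self.mouse_sd_log < 0:
            raise ValueError("noise_frac and mouse_sd_log must be >= 0")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")


def _draw_areas(cfg: CSAGenConfig, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(cfg.n_fibers)
    areas = cfg.median_um2 * np.exp(cfg.sigma_log * z)
    if cfg.mouse_sd_log > 0:
        mouse_effects = np.exp(cfg.mouse_sd_log * rng.standard_normal(cfg.n_mice))
        areas = areas * mouse_effects[_mouse_index(cfg.n_fibers, cfg.n_mice)]
    return areas


def _mouse_index(n_fibers: int, n_mice: int) -> np.ndarray:
    # round-robin assignment of pooled fibers to animals
    return np.arange(n_fibers) % n_mice


def gen_csa_samples(cfg: CSAGenConfig) -> tuple[CSASample, CSASample]:
    """Draw a (control, treated) fiber-CSA pair with a known true effect.

    The treated base sample is an independent draw from the control law
    (separate animals), or the identical draw when ``cfg.paired`` — the
    paired mode exists for exact-recovery tests.  The effect transform is
    applied to the base draw, then each treated fiber is perturbed
    multiplicatively by (1 + N(0, noise_frac)).
    """
    rng = np.random.default_rng(cfg.seed)
    control = _draw_areas(cfg, rng)
    base = control.copy() if cfg.paired else _draw_areas(cfg, rng)
    if cfg.effect_kind == "additive":
        treated = base + cfg.effect_value
    elif cfg.effect_kind == "multiplicative":
        treated = base * cfg.effect_value
    else:
        treated = base.copy()
    if cfg.noise_frac > 0:
        treated = treated * (1.0 + cfg.noise_frac * rng.standard_normal(treated.size))
    if np.any(treated <= 0):
        raise InvalidEffectError(
            "configured effect/noise produced non-positive fiber areas"
        )
    mice = _mouse_index(cfg.n_fibers, cfg.n_mice)
    return (
        CSASample(control, group="control", muscle=cfg.muscle,
                  mouse_ids=np.array([f"C{m + 1}" for m in mice])),
        CSASample(treated, group="treated", muscle=cfg.muscle,
                  mouse_ids=np.array([f"T{m + 1}" for m in mice])),
    )


# ---------------------------------------------------------------------------
# pharmacokinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKGenConfig:
    """One-compartment oral PK curve configuration.

    First-order absorption (ka) and elimination (ke) rate constants in 1/h,
    apparent volume of distribution V/F in L/kg; sampling grid defaults to
    the 0.5-6 h post-dose schedule.  cv_noise is the relative assay CV of
    multiplicative lognormal noise.
    """

    dose_mg_per_kg: float = 10.0
    ka_per_h: float = 2.0
    ke_per_h: float = 0.5
    v_over_f_L_per_kg: float = 5.0
    times_h: tuple[float, ...] = PK_SAMPLING_TIMES_H
    cv_noise: float = 0.0
    seed: int = 0
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        if self.ka_per_h <= 0 or self.ke_per_h <= 0 or self.v_over_f_L_per_kg <= 0:
            raise ValueError("rates and volume must be positive")
        if self.ka_per_h == self.ke_per_h:
            raise DegenerateModelError(
                "ka must differ from ke (flip-flop limit not supported)"
            )
        t = np.asarray(self.times_h, dtype=float)
        if t.size < 2 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times_h must be strictly increasing, first >= 0")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")


def one_compartment_conc(
    t: np.ndarray | float,
    dose_mg_per_kg: float,
    ka_per_h: float,
    ke_per_h: float,
    v_over_f_L_per_kg: float,
) -> np.ndarray:
    """Noiseless one-compartment oral concentration, ng/mL.

    C(t) = D ka / (V/F (ka - ke)) (e^{-ke t} - e^{-ka t}); D/(V/F) in
    mg/L equals 1000 ng/mL.
    """
    if ka_per_h == ke_per_h:
        raise DegenerateModelError("ka must differ from ke")
    t = np.asarray(t, dtype=float)
    scale = dose_mg_per_kg / v_over_f_L_per_kg * 1000.0  # mg/L -> ng/mL
    c = scale * ka_per_h / (ka_per_h - ke_per_h) * (
        np.exp(-ke_per_h * t) - np.exp(-ka_per_h * t)
    )
    return np.maximum(c, 0.0)


def gen_pk_profile(cfg: PKGenConfig) -> ConcSeries:
    """Generate one concentration-time curve, optionally noisy.

    Noise is multiplicative lognormal with unit mean and relative SD
    ``cv_noise``; a zero concentration (t = 0) stays exactly zero.
    """
    times = np.asarray(cfg.times_h, dtype=float)
    concs = one_compartment_conc(
        times, cfg.dose_mg_per_kg, cfg.ka_per_h, cfg.ke_per_h, cfg.v_over_f_L_per_kg
    )
    if cfg.cv_noise > 0:
        rng = np.random.default_rng(cfg.seed)
        sigma = np.sqrt(np.log1p(cfg.cv_noise**2))
        factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=times.size)
        concs = concs * factors
    return ConcSeries(cfg.matrix, times, concs, cfg.dose_mg_per_kg)


# ---------------------------------------------------------------------------
# histology image fixtures
# ---------------------------------------------------------------------------

def gen_histology_image(
    width: int,
    height: int,
    red_fraction: float,
    seed: int = 0,
    red_rgb: tuple[int, int, int] = FIBROSIS_RED,
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB,
) -> np.ndarray:
    """Synthetic Sirius-Red-like fixture with an exact red-pixel count.

    Exactly ``round(red_fraction * width * height)`` pixels carry the
    fibrosis-red triplet, placed uniformly at random by ``seed``; the rest
    are background.  Returns an (height, width, 3) uint8 array.
    """
    if not 0.0 <= red_fraction <= 1.0:
        raise ValueError("red_fraction must lie in [0, 1]")
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be positive")
    n = width * height
    n_red = int(round(red_fraction * n))
    img = np.empty((n, 3), dtype=np.uint8)
    img[:] = background_rgb
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=n_red, replace=False)
    img[idx] = red_rgb
    return img.reshape(height, width, 3)


def save_histology_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image, mode="RGB").save(path, format="PNG")


# ---------------------------------------------------------------------------
# functional tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionalGenConfig:
    """Grip / treadmill trajectory generator configuration.

    The mean grip force rises linearly by ``rise_frac`` up to ``peak_week``
    and then declines exponentially by ``decline_rate`` per week, mimicking
    the early-strength-gain-then-decline course of dystrophic mice.
    Treated arms multiply force (or exhaustion time) by
    ``treatment_effect``.  Treadmill shocks accrue as a Poisson process at
    ``shock_rate_per_min``; a session reaching ``shock_cap`` shocks is
    truncated there and flagged as capped.
    """

    n_mice: int = 9
    n_weeks: int = 16
    baseline_force: float = 120.0
    bw_g: float = 27.0
    bw_gain_g_per_week: float = 0.15
    treatment_effect: float = 1.0
    rise_frac: float = 0.15
    peak_week: int = 3
    decline_rate: float = 0.03
    trial_cv: float = 0.10
    mean_exhaustion_min: float = 12.0
    exhaustion_cv: float = 0.25
    shock_rate_per_min: float = 10.0
    shock_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.n_weeks < 1:
            raise ValueError("n_mice and n_weeks must be >= 1")
        if min(self.baseline_force, self.bw_g, self.treatment_effect,
               self.mean_exhaustion_min) <= 0:
            raise ValueError("forces, weights, times and effects must be positive")
        if not 0.0 <= self.decline_rate < 1.0:
            raise ValueError("decline_rate must lie in [0, 1)")
        if self.shock_cap not in (None, 600, 150):
            raise ValueError("shock_cap must be None, 600 or 150")


def _force_mean(cfg: FunctionalGenConfig, week: int) -> float:
    rise = 1.0 + cfg.rise_frac * min(week, cfg.peak_week) / max(cfg.peak_week, 1)
    decline = (1.0 - cfg.decline_rate) ** max(0, week - cfg.peak_week)
    return cfg.baseline_force * rise * decline


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def gen_grip_study(
    cfg: FunctionalGenConfig, arms: dict[str, float] | None = None
) -> pd.DataFrame:
    """Trial-level grip table: 5 force draws + one BW per mouse-week.

    ``arms`` maps group label to force multiplier; the default emits a
    vehicle arm (x1) and a treated arm (x cfg.treatment_effect).  Columns:
    mouse_id, group, week, trial, force, bw_g.
    """
    arms = arms or {"vehicle": 1.0, "treated": cfg.treatment_effect}
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group, mult in arms.items():
        for m in range(cfg.n_mice):
            mouse = f"{group}-{m + 1}"
            for week in range(cfg.n_weeks):
                mean = _force_mean(cfg, week) * mult
                forces = mean * _lognormal_factors(rng, cfg.trial_cv, 5)
                bw = cfg.bw_g + cfg.bw_gain_g_per_week * week
                for trial, force in enumerate(forces, start=1):
                    rows.append(
                        (mouse, group, week, trial, float(force), float(bw))
                    )
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", "week", "trial", "force", "bw_g"]
    )


def gen_treadmill_study(
    cfg: FunctionalGenConfig,
    arms: dict[str, float] | None = None,
    days: tuple[int, ...] = (0, 14, 28, 42, 56, 70, 84, 98),
) -> pd.DataFrame:
    """Session-level treadmill table with shock accrual and cap truncation.

    Exhaustion times are lognormal around a mean that declines like the
    grip trajectory; shocks over a run are Poisson at
    ``shock_rate_per_min``.  A mouse that would accumulate ``shock_cap``
    shocks is stopped at the expected arrival time of the cap-th shock and
    flagged.  Columns: mouse_id, group, day, time_min, shocks, capped.
    """
    arms = arms or {"vehicle": 1.0, "treated": cfg.treatment_effect}
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group, mult in arms.items():
        for m in range(cfg.n_mice):
            mouse = f"{group}-{m + 1}"
            for day in days:
                week = day // 7
                decline = (1.0 - cfg.decline_rate) ** max(0, week - cfg.peak_week)
                mean = cfg.mean_exhaustion_min * mult * decline
                t = float(mean * _lognormal_factors(rng, cfg.exhaustion_cv, 1)[0])
                shocks = int(rng.poisson(cfg.shock_rate_per_min * t))
                capped = False
                if cfg.shock_cap is not None and shocks >= cfg.shock_cap:
                    capped = True
                    shocks = cfg.shock_cap
                    t = min(t, cfg.shock_cap / cfg.shock_rate_per_min)
                rows.append((mouse, group, day, t, shocks, capped))
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", "day", "time_min", "shocks", "capped"]
    )


# ---------------------------------------------------------------------------
# histopathology findings
# ---------------------------------------------------------------------------

def gen_severity_cards(
    n_animals: int,
    group: str,
    severity_weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    extension_weights: tuple[float, float, float] = (0.4, 0.4, 0.2),
    presence_prob: float = 0.8,
    seed: int = 0,
) -> list[SeverityCard]:
    """Per-animal categorical lesion findings for the severity score.

    Each of the five lesion parameters is present with ``presence_prob``;
    severity and extension grades 1-3 are drawn from the given weights.
    """
    rng = np.random.default_rng(seed)
    cards = []
    for i in range(n_animals):
        findings = []
        for param in LESION_PARAMETERS:
            if rng.random() < presence_prob:
                sev = int(rng.choice((1, 2, 3), p=_norm(severity_weights)))
                ext = int(rng.choice((1, 2, 3), p=_norm(extension_weights)))
                findings.append(SeverityFinding(param, sev, ext))
        cards.append(SeverityCard(f"{group}-{i + 1}", tuple(findings)))
    return cards


def _norm(w: tuple[float, ...]) -> np.ndarray:
    a = np.asarray(w, dtype=float)
    return a / a.sum()


def gen_fiber_annotations(
    n_fibers: int = 100,
    centralized_prob: float = 0.6,
    median_um2: float = 500.0,
    sigma_log: float = 0.5,
    mouse_id: str = "M1",
    seed: int = 0,
) -> list[FiberAnnotation]:
    """Per-fiber annotations (area + central-nucleus flag) for one mouse.

    Emulates the 100-fibers-per-muscle manual annotation: lognormal areas
    and Bernoulli(centralized_prob) nuclear centralization.
    """
    if not 0.0 <= centralized_prob <= 1.0:
        raise ValueError("centralized_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    areas = median_um2 * np.exp(sigma_log * rng.standard_normal(n_fibers))
    central = rng.random(n_fibers) < centralized_prob
    return [
        FiberAnnotation(i + 1, float(a), bool(c), mouse_id)
        for i, (a, c) in enumerate(zip(areas, central))
    ]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_fiber_table(
    samples: list[CSASample], path: str | Path, sep: str = "\t"
) -> None:
    """Write pooled fiber areas as delimited text
    (mouse_id, group, muscle, area_um2)."""
    frames = []
    for s in samples:
        ids = s.mouse_ids if s.mouse_ids is not None else np.repeat("NA", s.n)
        frames.append(
            pd.DataFrame(
                {
                    "mouse_id": ids,
                    "group": s.group,
                    "muscle": s.muscle,
                    "area_um2": s.areas,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_fiber_table(
    path: str | Path, group: str | None = None, sep: str = "\t"
) -> CSASample:
    """Read a fiber table back into a single (optionally filtered) sample."""
    df = pd.read_csv(path, sep=sep)
    if group is not None:
        df = df[df["group"] == group]
    if df.empty:
        raise ValueError(f"no fibers for group {group!r} in {path}")
    muscles = df["muscle"].unique()
    return CSASample(
        df["area_um2"].to_numpy(dtype=float),
        group=group or str(df["group"].iloc[0]),
        muscle=str(muscles[0]) if len(muscles) == 1 else "",
        mouse_ids=df["mouse_id"].to_numpy(),
    )


def write_pk_table(
    series_list: list[ConcSeries], path: str | Path, sep: str = "\t"
) -> None:
    """Write concentration series as delimited text
    (matrix, dose_mg_per_kg, time_h, conc_ng_ml)."""
    frames = [
        pd.DataFrame(
            {
                "matrix": s.matrix,
                "dose_mg_per_kg": s.dose_mg_per_kg,
                "time_h": s.times,
                "conc_ng_ml": s.concs,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_pk_table(path: str | Path, sep: str = "\t") -> list[ConcSeries]:
    """Read a PK table into one series per matrix x dose."""
    df = pd.read_csv(path, sep=sep)
    out = []
    for (matrix, dose), g in df.groupby(["matrix", "dose_mg_per_kg"], sort=True):
        g = g.sort_values("time_h")
        out.append(
            ConcSeries(
                str(matrix),
                g["time_h"].to_numpy(dtype=float),
                g["conc_ng_ml"].to_numpy(dtype=float),
                float(dose),
            )
        )
    return out
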