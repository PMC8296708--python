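"""End-to-end study orchestration and routine group-comparison statistics.

``run_study`` wires the stages together on synthetic data: fiber-CSA
generation and shift analysis, PK curves with NCA and matrix ratios,
histology fixtures with fibrosis / centralized-nuclei / severity scoring,
and the functional-test tables with their summaries.  The module also
carries the routine statistics applied across readouts: one-way ANOVA with
Bonferroni-adjusted pairwise comparisons, and the plain two-factor ANOVA
for arm x time readouts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from . import functional_tests as ft
from . import histopathology as histo
from . import pharmacokinetics as pkin
from . import synthetic as syn
from .csa_shift import analyze_pair

__all__ = [
    "StudyConfig",
    "GroupSummary",
    "AnovaResult",
    "InsufficientDataError",
    "UnbalancedDesignError",
    "one_way_anova_bonferroni",
    "two_way_anova",
    "group_summary",
    "run_study",
]


class InsufficientDataError(ValueError):
    """A group has too few observations for the requested comparison."""


class UnbalancedDesignError(ValueError):
    """Factorial layout has empty cells beyond tolerance."""


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- standard error for one metric in one arm."""

    arm: str
    metric: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1 or self.se < 0:
            raise ValueError("n must be >= 1 and se >= 0")


def group_summary(arm: str, metric: str, values) -> GroupSummary:
    """Summarise one arm's values as mean +/- s.e. (ddof = 1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InsufficientDataError("no values")
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(arm, metric, float(v.mean()), se, int(v.size))


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA F-test plus Bonferroni-adjusted pairwise t-tests."""

    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_raw, p_bonferroni

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def one_way_anova_bonferroni(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    family: str = "vs_control",
    control: str | None = None,
) -> AnovaResult:
    """Classical one-way ANOVA with Bonferroni-corrected pairwise t-tests.

    ``family`` selects the comparison family: ``"vs_control"`` (default;
    every group against ``control``, the first label if unspecified) or
    ``"all_pairs"``.  Each raw two-sample t-test p-value is multiplied by
    the family size and capped at 1.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than 2 values")
    f_stat, p_value = stats.f_oneway(*arrays.values())
    if np.isnan(f_stat):  # all groups identical-constant: no variance anywhere
        f_stat, p_value = 0.0, 1.0
    labels = list(arrays)
    if family == "vs_control":
        ref = control if control is not None else labels[0]
        if ref not in arrays:
            raise ValueError(f"control group {ref!r} not found")
        pairs = [(ref, g) for g in labels if g != ref]
    elif family == "all_pairs":
        pairs = list(combinations(labels, 2))
    else:
        raise ValueError(f"unknown family {family!r}")
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p_raw = stats.ttest_ind(arrays[a], arrays[b])
        if np.isnan(p_raw):
            t, p_raw = 0.0, 1.0
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t_stat": float(t),
                "p_raw": float(p_raw),
                "p_bonferroni": min(1.0, float(p_raw) * m),
                "significant": min(1.0, float(p_raw) * m) <= alpha,
            }
        )
    n_total = sum(v.size for v in arrays.values())
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        pairwise=pd.DataFrame(rows),
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str = "group",
    factor_b: str = "time",
    max_empty_cell_frac: float = 0.0,
) -> pd.DataFrame:
    """Two-factor ANOVA (main effects + interaction) on a long-format table.

    Returns the type-II ANOVA table (sum_sq, df, F, PR(>F)) indexed by
    effect.  With a single level of ``factor_b`` the model degenerates to
    the one-way ANOVA on ``factor_a``.  Cells empty beyond
    ``max_empty_cell_frac`` of the layout raise ``UnbalancedDesignError``.
    """
    df = data[[value, factor_a, factor_b]].dropna()
    levels_a = df[factor_a].nunique()
    levels_b = df[factor_b].nunique()
    if levels_a < 2:
        raise InsufficientDataError(f"factor {factor_a!r} needs >= 2 levels")
    cells = df.groupby([factor_a, factor_b], observed=True).size()
    n_empty = levels_a * levels_b - len(cells)
    if n_empty > max_empty_cell_frac * levels_a * levels_b:
        raise UnbalancedDesignError(f"{n_empty} empty cells in the layout")
    if levels_b < 2:
        model = ols(f"Q('{value}') ~ C(Q('{factor_a}'))", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        table.index = [factor_a, "Residual"]
        return table
    model = ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "Residual"]
    return table


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration of a full synthetic two-arm study.

    Stage configs are the generator configs of the respective modules; the
    ``seed`` deterministically derives every stage's seed, so two runs with
    the same config produce identical report bundles.
    """

    arms: tuple[str, str] = ("vehicle", "treated")
    csa: syn.CSAGenConfig = field(
        default_factory=lambda: syn.CSAGenConfig(
            effect_kind="multiplicative", effect_value=1.72, noise_frac=0.05
        )
    )
    pk: syn.PKGenConfig = field(default_factory=syn.PKGenConfig)
    pk_doses: tuple[float, ...] = syn.PK_DOSES_MG_PER_KG
    blood_plasma_scale: float = 1.6
    muscle_plasma_scale: float = 4.5
    tissue_correction: pkin.TissueCorrectionParams = field(
        default_factory=pkin.TissueCorrectionParams
    )
    functional: syn.FunctionalGenConfig = field(
        default_factory=lambda: syn.FunctionalGenConfig(treatment_effect=1.3)
    )
    fibrosis_red_fraction: dict[str, float] = field(
        default_factory=lambda: {"vehicle": 0.30, "treated": 0.20}
    )
    centralized_prob: dict[str, float] = field(
        default_factory=lambda: {"vehicle": 0.77, "treated": 0.65}
    )
    n_histo_mice: int = 5
    histo_image_px: int = 120
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValueError("need at least 2 arms")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "arms" in kwargs:
            kwargs["arms"] = tuple(kwargs["arms"])
        if "pk_doses" in kwargs:
            kwargs["pk_doses"] = tuple(kwargs["pk_doses"])
        if "csa" in kwargs:
            kwargs["csa"] = syn.CSAGenConfig(**kwargs["csa"])
        if "pk" in kwargs:
            kwargs["pk"] = syn.PKGenConfig(
                **{
                    **kwargs["pk"],
                    "times_h": tuple(
                        kwargs["pk"].get("times_h", syn.PK_SAMPLING_TIMES_H)
                    ),
                }
            )
        if "functional" in kwargs:
            kwargs["functional"] = syn.FunctionalGenConfig(**kwargs["functional"])
        if "tissue_correction" in kwargs:
            kwargs["tissue_correction"] = pkin.TissueCorrectionParams(
                **kwargs["tissue_correction"]
            )
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage_seeds(seed: int, n: int) -> list[int]:
    # deterministic per-stage seeds derived from the study seed
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]  # keep below 2**31


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Generate a full synthetic study and run every analysis stage.

    Returns a JSON-serialisable report bundle; when ``out_dir`` is given,
    writes ``report.json`` plus the stage tables as tab-delimited text.
    """
    seeds = _stage_seeds(config.seed, 6)
    report: dict = {"seed": config.seed, "arms": list(config.arms)}
    tables: dict[str, pd.DataFrame] = {}

    # --- fiber CSA shift analysis -------------------------------------
    csa_cfg = syn.CSAGenConfig(**{**asdict(config.csa), "seed": seeds[0]})
    control, treated = syn.gen_csa_samples(csa_cfg)
    csa_report = analyze_pair(control, treated, alpha=config.alpha)
    report["csa"] = csa_report.to_dict()
    tables["fibers"] = pd.DataFrame(
        {
            "mouse_id": np.concatenate([control.mouse_ids, treated.mouse_ids]),
            "group": [control.group] * control.n + [treated.group] * treated.n,
            "muscle": csa_cfg.muscle,
            "area_um2": np.concatenate([control.areas, treated.areas]),
        }
    )

    # --- pharmacokinetics ---------------------------------------------
    pk_section: dict = {"per_dose": [], "auc_ratios": {}}
    nca_by_dose: dict[float, pkin.NCAResult] = {}
    pk_rows = []
    for dose in config.pk_doses:
        base = syn.PKGenConfig(
            **{
                **asdict(config.pk),
                "dose_mg_per_kg": dose,
                "seed": seeds[1],
                "times_h": tuple(config.pk.times_h),
            }
        )
        plasma = syn.gen_pk_profile(base)
        blood = pkin.ConcSeries(
            "blood", plasma.times, plasma.concs * config.blood_plasma_scale, dose
        )
        muscle = pkin.ConcSeries(
            "muscle_homogenate",
            plasma.times,
            plasma.concs * config.muscle_plasma_scale,
            dose,
        )
        res = {
            "plasma": pkin.nca(plasma),
            "blood": pkin.nca(blood),
            "muscle": pkin.nca(muscle),
        }
        nca_by_dose[dose] = res["plasma"]
        pk_section["per_dose"].append(
            {
                "dose_mg_per_kg": dose,
                "nca": {k: v.to_dict() for k, v in res.items()},
                "blood_plasma_auc_ratio": pkin.auc_ratio(res["blood"], res["plasma"]),
                "muscle_plasma_auc_ratio": pkin.auc_ratio(res["muscle"], res["plasma"]),
            }
        )
        for s in (plasma, blood, muscle):
            pk_rows.append(
                pd.DataFrame(
                    {
                        "matrix": s.matrix,
                        "dose_mg_per_kg": dose,
                        "time_h": s.times,
                        "conc_ng_ml": s.concs,
                    }
                )
            )
    dr = pkin.dose_response_summary(nca_by_dose)
    pk_section["dose_response"] = dr.to_dict(orient="records")
    report["pk"] = pk_section
    tables["pk_series"] = pd.concat(pk_rows, ignore_index=True)

    # --- histopathology -------------------------------------------------
    histo_section: dict = {"fibrosis": {}, "centralized_nuclei": {}, "mts": {}}
    fib_values: dict[str, list[float]] = {}
    cn_values: dict[str, list[float]] = {}
    rng_fields = np.random.default_rng(seeds[2])
    for ai, arm in enumerate(config.arms):
        frac = config.fibrosis_red_fraction.get(arm, 0.25)
        per_mouse_fib = []
        per_mouse_cn = []
        for mi in range(config.n_histo_mice):
            fields = []
            for fi in range(3):
                img = syn.gen_histology_image(
                    config.histo_image_px,
                    config.histo_image_px,
                    min(1.0, max(0.0, frac * (1 + 0.1 * rng_fields.standard_normal()))),
                    seed=int(rng_fields.integers(2**31)),
                )
                fields.append(histo.fibrosis_fraction(img))
            per_mouse_fib.append(histo.muscle_fibrosis(fields))
            ann = syn.gen_fiber_annotations(
                100,
                config.centralized_prob.get(arm, 0.6),
                mouse_id=f"{arm}-{mi + 1}",
                seed=int(rng_fields.integers(2**31)),
            )
            per_mouse_cn.append(histo.centralized_nuclei_pct(ann))
        fib_values[arm] = per_mouse_fib
        cn_values[arm] = per_mouse_cn
        cards = syn.gen_severity_cards(
            config.n_histo_mice, arm, seed=seeds[3] + ai
        )
        histo_section["fibrosis"][arm] = group_summary(
            arm, "fibrosis_pct", per_mouse_fib
        ).__dict__
        histo_section["centralized_nuclei"][arm] = group_summary(
            arm, "centralized_pct", per_mouse_cn
        ).__dict__
        histo_section["mts"][arm] = histo.group_mts(cards)
    histo_section["fibrosis_anova"] = one_way_anova_bonferroni(
        {k: np.asarray(v) for k, v in fib_values.items()}, config.alpha
    ).to_dict()
    histo_section["centralized_anova"] = one_way_anova_bonferroni(
        {k: np.asarray(v) for k, v in cn_values.items()}, config.alpha
    ).to_dict()
    report["histopathology"] = histo_section

    # --- functional tests -----------------------------------------------
    fn_cfg = syn.FunctionalGenConfig(
        **{**asdict(config.functional), "seed": seeds[4]}
    )
    grip = syn.gen_grip_study(fn_cfg)
    tread = syn.gen_treadmill_study(fn_cfg)
    grip_sum = ft.grip_group_summary(grip)
    tread_sum = ft.treadmill_group_summary(tread)
    per_session = (
        grip.groupby(["group", "mouse_id", "week"])
        .apply(lambda g: g["force"].max() / g["bw_g"].iloc[0], include_groups=False)
        .rename("fnmax")
        .reset_index()
    )
    fn_anova = two_way_anova(per_session, "fnmax", "group", "week")
    tread_df = tread.assign(distance_m=tread["time_min"].map(ft.treadmill_distance))
    tr_anova = two_way_anova(tread_df, "distance_m", "group", "day")
    report["functional"] = {
        "grip_summary": grip_sum.to_dict(orient="records"),
        "treadmill_summary": tread_sum.to_dict(orient="records"),
        "fnmax_anova": _anova_table_dict(fn_anova),
        "distance_anova": _anova_table_dict(tr_anova),
    }
    tables["grip"] = grip
    tables["treadmill"] = tread

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return report


def _anova_table_dict(table: pd.DataFrame) -> dict:
    return {
        str(idx): {
            "F": None if np.isnan(row.get("F", np.nan)) else float(row["F"]),
            "p": None
            if np.isnan(row.get("PR(>F)", np.nan))
            else float(row["PR(>F)"]),
            "df": float(row["df"]),
        }
        for idx, row in table.iterrows()
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
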