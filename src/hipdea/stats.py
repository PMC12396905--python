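"""Factorial study orchestration and the sensitivity statistics.

The study grid crosses 2 cartilage models x 3 gait loading profiles into 6
scenarios, each solved pre- and postoperatively over the cohort (7 load
instances per solve: 84 instance-solves per subject). Diverging (subluxing)
hips are excluded from a scenario wholesale. The sensitivity machinery is
the paper-style trio: paired t-tests on pre/post values, a weighted Pearson
correlation grid between the 8 stress metrics and the 5 radiographic
measures (pre/post pooled with group-balanced weights), and forward
stepwise regression with F-in 3.84 / F-out 2.71.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cartilage import (
    ACETABULAR,
    ShivannaParams,
    default_dysplastic_map,
    nishii_offset,
    shivanna_offset,
)
from .cohort import MEASURE_NAMES, SubjectRecord, generate_acetabulum
from .dea import (
    ContactModel,
    FemoralSurface,
    MaterialParams,
    SequenceDivergence,
    SolverSettings,
    solve_sequence,
)
from .gait import GLP_FAMILIES, discretize, synth_glp
from .metrics import METRIC_NAMES, MetricThresholds, compute_all

CARTILAGE_MODELS = ("nishii", "shivanna")
GLP_NAMES = tuple(GLP_FAMILIES)
SCENARIOS = tuple(itertools.product(CARTILAGE_MODELS, GLP_NAMES))
TREATMENTS = ("pre", "post")


@dataclass
class StudySettings:
    material: MaterialParams = field(default_factory=MaterialParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    thresholds: MetricThresholds = field(default_factory=MetricThresholds)
    shivanna: ShivannaParams = field(default_factory=ShivannaParams)
    femoral_thickness: float = 1.0  # mm, uniform-offset femoral cartilage
    stance_duration_s: float = 0.6
    element_size: float | None = None  # override geometry target, mm


@dataclass
class StepwiseConfig:
    f_in: float = 3.84
    f_out: float = 2.71
    candidates: tuple = (
        "AAA", "ACEA", "AI", "FHEI", "LCEA",
        "sex", "age", "height", "weight", "acetabular_radius",
    )

    def __post_init__(self) -> None:
        if not self.f_in > self.f_out > 0:
            raise ValueError("need f_in > f_out > 0")


def study_plan(subject: SubjectRecord) -> list[tuple]:
    """Enumerate every DEA instance-solve for one subject."""
    return [
        (subject.id, subject.side, cart, glp, treatment, k)
        for (cart, glp) in SCENARIOS
        for treatment in TREATMENTS
        for k in range(1, 8)
    ]


@dataclass
class StudyResult:
    metrics: pd.DataFrame  # one row per converged (hip, scenario, treatment)
    divergences: pd.DataFrame  # one row per excluded (hip, scenario, treatment)

    def sample_sizes(self) -> pd.DataFrame:
        if len(self.metrics) == 0:
            return pd.DataFrame(columns=["cartilage", "glp", "treatment", "n"])
        return (
            self.metrics.groupby(["cartilage", "glp", "treatment"])
            .size()
            .rename("n")
            .reset_index()
        )


def _acetabular_layer(record: SubjectRecord, treatment: str, cartilage: str,
                      settings: StudySettings):
    geometry = record.pre_geometry if treatment == "pre" else record.post_geometry
    if settings.element_size is not None:
        from dataclasses import replace

        geometry = replace(geometry, target_element_size=settings.element_size)
    cup, frame = generate_acetabulum(geometry)
    if cartilage == "shivanna":
        layer = shivanna_offset(cup, frame, settings.shivanna, side=ACETABULAR)
    elif cartilage == "nishii":
        layer = nishii_offset(cup, frame, default_dysplastic_map())
    else:
        raise ValueError(f"unknown cartilage model {cartilage!r}")
    return layer, frame, geometry


def run_study(
    cohort: list[SubjectRecord],
    settings: StudySettings | None = None,
    scenarios=SCENARIOS,
) -> StudyResult:
    """Solve the full factorial for every hip; collect metrics/divergences.

    The femoral side uses the uniform-offset cartilage on the near-spherical
    synthetic head, which reduces to an exact sphere model (the mesh-based
    femoral path is exercised in the contact tests; the cohort default has
    zero asphericity noise).
    """
    settings = settings or StudySettings()
    metric_rows = []
    divergence_rows = []
    for record in cohort:
        glp_instances = {
            name: discretize(synth_glp(name), record.weight, settings.stance_duration_s)
            for name in {g for _, g in scenarios}
        }
        for cartilage in {c for c, _ in scenarios}:
            for treatment in TREATMENTS:
                layer, frame, geometry = _acetabular_layer(
                    record, treatment, cartilage, settings
                )
                femur = FemoralSurface.sphere(
                    geometry.head_radius, settings.femoral_thickness
                )
                model = ContactModel(layer, femur, frame, settings.material)
                for glp in (g for c, g in scenarios if c == cartilage):
                    out = solve_sequence(model, glp_instances[glp], settings.solver)
                    key = dict(
                        id=record.id, side=record.side, cartilage=cartilage,
                        glp=glp, treatment=treatment,
                    )
                    if isinstance(out, SequenceDivergence):
                        divergence_rows.append(
                            dict(**key,
                                 failed_instances=";".join(map(str, out.failed_instances)),
                                 reasons=";".join(out.reasons))
                        )
                    else:
                        mset = compute_all(out, settings.thresholds)
                        metric_rows.append({**key, **mset.as_dict()})
    metrics = pd.DataFrame(metric_rows)
    divergences = pd.DataFrame(
        divergence_rows,
        columns=["id", "side", "cartilage", "glp", "treatment",
                 "failed_instances", "reasons"],
    )
    return StudyResult(metrics, divergences)


# --------------------------------------------------------------------------
# paired tests
# --------------------------------------------------------------------------


def paired_t(pre, post) -> tuple[float, float, float]:
    """Dependent-samples t-test; returns (t, two-sided p, mean difference)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = post - pre
    mean = float(diff.mean())
    if float(diff.std(ddof=1)) == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, 0.0
        return float(np.sign(mean)) * np.inf, 0.0, mean
    t, p = sps.ttest_rel(post, pre)
    return float(t), float(p), mean


# --------------------------------------------------------------------------
# weighted correlation
# --------------------------------------------------------------------------


def weighted_pearson(x, y, weights=None) -> tuple[float, float]:
    """Weighted Pearson correlation and its p-value.

    Significance uses the t transform with the Kish effective sample size
    (sum w)^2 / sum w^2. With equal weights this reduces to the ordinary
    Pearson correlation and test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d samples, n >= 3")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match the data")
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return np.nan, np.nan
    r = float(cov / np.sqrt(vx * vy))
    n_eff = 1.0 / float(w @ w)
    if n_eff <= 2 or abs(r) >= 1.0:
        return r, 0.0 if abs(r) >= 1.0 else np.nan
    t = r * np.sqrt((n_eff - 2.0) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n_eff - 2.0)
    return r, float(p)


def _balanced_weights(treatment: np.ndarray) -> np.ndarray:
    """Pre and post groups each carry half the total weight.

    This is the divergence-skew guard: with uneven converging sample sizes
    the pre-op pairs share weight W/n_pre and post-op pairs W/n_post.
    """
    w = np.empty(len(treatment), dtype=float)
    for grp in ("pre", "post"):
        mask = treatment == grp
        if mask.sum() == 0:
            raise ValueError(f"no {grp} observations")
        w[mask] = 1.0 / mask.sum()
    return w


def correlation_grid(
    result: StudyResult,
    cohort: list[SubjectRecord],
    alpha: float = 0.05,
    min_obs: int = 3,
) -> pd.DataFrame:
    """R and p for every (metric, measure, scenario) cell: 8 x 5 x 6 = 240.

    Pre and post observations are pooled; each hip contributes its
    treatment-matched radiographic measure, with group-balanced weights.
    Cells with fewer than ``min_obs`` joint observations are marked missing.
    """
    measure_lookup = {
        (r.id, r.side, phase): getattr(r, f"{phase}_measures").as_dict()
        for r in cohort
        for phase in TREATMENTS
    }
    rows = []
    for cart, glp in SCENARIOS:
        sub = result.metrics[
            (result.metrics.cartilage == cart) & (result.metrics.glp == glp)
        ]
        for metric in METRIC_NAMES:
            for measure in MEASURE_NAMES:
                row = dict(cartilage=cart, glp=glp, metric=metric, measure=measure)
                if len(sub) >= min_obs and set(sub.treatment) == set(TREATMENTS):
                    y = sub[metric].to_numpy()
                    x = np.array(
                        [
                            measure_lookup[(i, s, tr)][measure]
                            for i, s, tr in zip(sub.id, sub.side, sub.treatment)
                        ]
                    )
                    w = _balanced_weights(sub.treatment.to_numpy())
                    r, p = weighted_pearson(x, y, w)
                    row.update(R=r, p=p, n=len(sub), significant=bool(p < alpha))
                else:
                    row.update(R=np.nan, p=np.nan, n=len(sub), significant=False)
                rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# forward stepwise regression
# --------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    selected: list[str]
    intercept: float
    coefficients: dict[str, float]
    steps: list[dict]  # action, variable, r_squared, r_squared_change
    barred: list[str]  # collinear candidates never allowed in

    @property
    def r_squared(self) -> float:
        return self.steps[-1]["r_squared"] if self.steps else 0.0


def _ols_rss(y: np.ndarray, cols: list[np.ndarray]) -> tuple[float, np.ndarray, int]:
    design = np.column_stack([np.ones(len(y))] + cols)
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), beta, rank


def forward_stepwise(
    y, X: pd.DataFrame, cfg: StepwiseConfig | None = None
) -> StepwiseResult:
    """Forward stepwise OLS with partial-F entry/removal.

    At each step the candidate with the largest partial F enters when
    F >= f_in; entered variables whose partial F falls below f_out are
    removed. Perfectly collinear candidates are barred from entry. A
    numerical perfect-fit guard stops entry once the residual R-squared
    deficit is below 1e-9 (partial F is undefined on a numerically exact
    fit).
    """
    cfg = cfg or StepwiseConfig()
    y = np.asarray(y, dtype=float)
    names = [c for c in cfg.candidates if c in X.columns]
    data = {c: np.asarray(X[c], dtype=float) for c in names}
    n = len(y)
    if any(len(v) != n for v in data.values()):
        raise ValueError("candidate columns must match y in length")

    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return StepwiseResult([], float(y.mean()), {}, [], [])

    selected: list[str] = []
    barred: list[str] = []
    steps: list[dict] = []
    rss_current, beta, _ = _ols_rss(y, [])
    step_no = 0

    while True:
        if n <= len(selected) + 2:
            break
        r2_current = 1.0 - rss_current / tss
        if 1.0 - r2_current < 1e-9:
            break  # numerically perfect fit; partial F undefined
        # entry phase
        best_name, best_f, best_rss = None, -np.inf, None
        for name in names:
            if name in selected or name in barred:
                continue
            cols = [data[c] for c in selected] + [data[name]]
            rss_new, _, rank = _ols_rss(y, cols)
            if rank < len(cols) + 1:
                barred.append(name)
                continue
            df_resid = n - len(cols) - 1
            if df_resid <= 0:
                continue
            f = (rss_current - rss_new) / max(rss_new / df_resid, 1e-300)
            if f > best_f:
                best_name, best_f, best_rss = name, f, rss_new
        if best_name is None or best_f < cfg.f_in:
            break
        selected.append(best_name)
        rss_current = best_rss
        step_no += 1
        r2 = 1.0 - rss_current / tss
        prev_r2 = steps[-1]["r_squared"] if steps else 0.0
        steps.append(
            dict(step=step_no, action="enter", variable=best_name,
                 partial_f=best_f, r_squared=r2, r_squared_change=r2 - prev_r2)
        )
        # removal phase
        removed = True
        while removed and len(selected) > 1:
            removed = False
            worst_name, worst_f, worst_rss = None, np.inf, None
            df_resid = n - len(selected) - 1
            for name in selected:
                others = [data[c] for c in selected if c != name]
                rss_wo, _, _ = _ols_rss(y, others)
                f = (rss_wo - rss_current) / max(rss_current / df_resid, 1e-300)
                if f < worst_f:
                    worst_name, worst_f, worst_rss = name, f, rss_wo
            if worst_f < cfg.f_out:
                selected.remove(worst_name)
                rss_current = worst_rss
                step_no += 1
                r2 = 1.0 - rss_current / tss
                prev_r2 = steps[-1]["r_squared"]
                steps.append(
                    dict(step=step_no, action="remove", variable=worst_name,
                         partial_f=worst_f, r_squared=r2,
                         r_squared_change=r2 - prev_r2)
                )
                removed = True

    _, beta, _ = _ols_rss(y, [data[c] for c in selected])
    coefficients = {name: float(beta[i + 1]) for i, name in enumerate(selected)}
    return StepwiseResult(selected, float(beta[0]), coefficients, steps, barred)


def candidate_matrix(cohort: list[SubjectRecord], treatment: str = "pre") -> pd.DataFrame:
    """Per-hip predictor matrix: measures + covariates (sex coded F=0, M=1)."""
    rows = []
    for r in cohort:
        m = getattr(r, f"{treatment}_measures").as_dict()
        rows.append(
            dict(id=r.id, side=r.side, **m, sex=0.0 if r.sex == "F" else 1.0,
                 age=r.age, height=r.height, weight=r.weight,
                 acetabular_radius=r.acetabular_radius)
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# treatment effects
# --------------------------------------------------------------------------


def summarize_treatment_effects(result: StudyResult) -> pd.DataFrame:
    """Paired pre/post comparison per metric per scenario.

    Only hips converging in both treatments of a scenario contribute; the
    output holds mean pre, mean post, relative change % and the paired-t p.
    """
    rows = []
    m = result.metrics
    if len(m) == 0:
        raise ValueError("no converged metrics to summarise")
    for cart, glp in SCENARIOS:
        sub = m[(m.cartilage == cart) & (m.glp == glp)]
        pre = sub[sub.treatment == "pre"].set_index(["id", "side"])
        post = sub[sub.treatment == "post"].set_index(["id", "side"])
        common = pre.index.intersection(post.index)
        if len(common) < 2:
            continue
        for metric in METRIC_NAMES:
            a = pre.loc[common, metric].to_numpy(dtype=float)
            b = post.loc[common, metric].to_numpy(dtype=float)
            t, p, mean_diff = paired_t(a, b)
            mean_pre = float(a.mean())
            rel = 100.0 * mean_diff / mean_pre if mean_pre != 0 else np.nan
            rows.append(
                dict(cartilage=cart, glp=glp, metric=metric, n=len(common),
                     mean_pre=mean_pre, mean_post=float(b.mean()),
                     relative_change_pct=rel, t=t, p=p)
            )
    if not rows:
        raise ValueError("no scenario had paired converged hips")
    return pd.DataFrame(rows)
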