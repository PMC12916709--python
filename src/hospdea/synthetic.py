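"""Synthetic hospital panels with known ground-truth efficiency.

The generator draws *efficient* input bundles, maps them through a smooth
reference technology to frontier outputs, and then inflates all inputs
radially by 1/theta_true, so the constructed radial input-efficiency of every
DMU is known exactly. The technology is Cobb-Douglas in a single latent
output, split into the observed outputs by fixed positive weights:

    Q = A * prod_k x_k^alpha_k,      y_r = w_r * Q.

The scale elasticity sum(alpha) selects the returns-to-scale regime: 1 gives
constant returns, < 1 decreasing. (Elasticities above 1 produce a non-concave
frontier whose convex hull exceeds the true technology, so DEA scores are not
inner-bounded there; the guarantee and its tests apply to sum(alpha) <= 1.)

Outputs carry no measurement noise by default, matching the deterministic
frontier assumption of DEA; an optional crisis shock multiplies outputs by a
factor delta in designated years, emulating the pandemic-era suppression of
hospital activity at unchanged capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dea import DMUSet
from .errors import DegenerateSampleError
from .panel import HospitalYearRecord, PanelDataset

__all__ = [
    "TechnologySpec",
    "Shock",
    "SyntheticPanel",
    "HOSPITAL_TECH",
    "SIMPLE_CRS_TECH",
    "generate_panel",
    "generate_dmu_sample",
    "generate_second_stage",
]


@dataclass(frozen=True)
class TechnologySpec:
    """Ground-truth production technology for the generator."""

    alphas: tuple[float, ...]  # per-input elasticities (>= 0)
    output_weights: tuple[float, ...]  # positive split of the latent output
    input_ranges: tuple[tuple[float, float], ...]  # efficient-bundle ranges
    scale: float = 1.0  # frontier productivity constant A
    inefficiency: tuple = ("half_normal", 0.15)  # or ("uniform", a, b)

    def __post_init__(self) -> None:
        if len(self.alphas) != len(self.input_ranges):
            raise ValueError("one range per input required")
        if any(a < 0 for a in self.alphas):
            raise ValueError("elasticities must be non-negative")
        if any(w <= 0 for w in self.output_weights):
            raise ValueError("output weights must be positive")
        kind = self.inefficiency[0]
        if kind == "uniform":
            _, a, b = self.inefficiency
            if not (0 < a <= b <= 1):
                raise ValueError("uniform inefficiency support must lie in (0, 1]")
        elif kind != "half_normal":
            raise ValueError(f"unknown inefficiency distribution {kind!r}")

    @property
    def m(self) -> int:
        return len(self.alphas)

    @property
    def s(self) -> int:
        return len(self.output_weights)

    @property
    def scale_elasticity(self) -> float:
        return float(sum(self.alphas))


@dataclass(frozen=True)
class Shock:
    """Output-suppressing crisis shock in designated years."""

    years: tuple[int, ...] = (2020, 2021)
    delta: float = 0.7  # output multiplier in shock years

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError("delta must be in (0, 1]")


#: Default technology emulating the study panel: 4 operational inputs
#: (beds, physicians, nurses, other staff) in the observed magnitude ranges,
#: two outputs (hospitalisations and surgical procedures), constant returns.
HOSPITAL_TECH = TechnologySpec(
    alphas=(0.40, 0.20, 0.25, 0.15),
    output_weights=(1.0, 0.30),
    input_ranges=((400, 650), (150, 300), (450, 650), (270, 680)),
    scale=70.0,
)

#: Minimal single-input single-output CRS technology for calibration studies.
SIMPLE_CRS_TECH = TechnologySpec(
    alphas=(1.0,),
    output_weights=(1.0,),
    input_ranges=((200.0, 600.0),),
    scale=50.0,
)


@dataclass
class SyntheticPanel:
    panel: PanelDataset
    theta_true: dict[tuple[str, int], float]
    tech: TechnologySpec
    shock: Shock | None = None


def _draw_theta(tech: TechnologySpec, size: int, rng: np.random.Generator,
                max_redraws: int = 100) -> np.ndarray:
    kind = tech.inefficiency[0]
    out = np.empty(size)
    for i in range(size):
        for attempt in range(max_redraws):
            if kind == "half_normal":
                t = float(np.exp(-abs(rng.normal(0.0, tech.inefficiency[1]))))
            else:
                _, a, b = tech.inefficiency
                t = float(rng.uniform(a, b))
            if 0.0 < t <= 1.0:
                out[i] = t
                break
        else:
            raise DegenerateSampleError(
                "could not draw an inefficiency value inside (0, 1]"
            )
    return out


def _frontier(tech: TechnologySpec, x_eff: np.ndarray) -> np.ndarray:
    """Frontier outputs (s, n) from efficient inputs (m, n)."""
    logq = np.log(tech.scale) + np.asarray(tech.alphas) @ np.log(x_eff)
    q = np.exp(logq)
    return np.outer(tech.output_weights, q)


def generate_dmu_sample(
    tech: TechnologySpec, n: int, seed: int = 0,
    theta_true: np.ndarray | None = None,
) -> tuple[DMUSet, np.ndarray]:
    """A bare DMU set plus its ground-truth radial efficiencies."""
    rng = np.random.default_rng(seed)
    lo = np.array([r[0] for r in tech.input_ranges])
    hi = np.array([r[1] for r in tech.input_ranges])
    x_eff = rng.uniform(lo[:, None], hi[:, None], size=(tech.m, n))
    y = _frontier(tech, x_eff)
    if theta_true is None:
        theta_true = _draw_theta(tech, n, rng)
    x_obs = x_eff / theta_true
    labels = [f"D{i+1}" for i in range(n)]
    return DMUSet(inputs=x_obs, outputs=y, labels=labels), theta_true


# Documented mapping of generated quantities onto the hospital schema:
#   input 1 -> beds, input 2 -> physicians (total), input 3 -> nurses (total),
#   input 4 -> other medical staff; output 1 -> hospitalisations,
#   output 2 -> surgical procedures. Staff totals are split into salaried and
#   contract headcounts by a drawn contract share (the split does not affect
#   the DMU matrices, which aggregate the two forms). Financial lines follow
#   fixed per-unit rates chosen to land in the magnitude range of real
#   regional-hospital accounts (thousand PLN).
_COST_RATES = {"physicians": 150.0, "nurses": 90.0, "other": 70.0, "beds": 40.0}
_REVENUE_RATES = {"hospitalisations": 4.5, "surgical": 2.0}


def generate_panel(
    tech: TechnologySpec = HOSPITAL_TECH,
    n_hospitals: int = 3,
    years: tuple[int, ...] = tuple(range(2015, 2025)),
    shock: Shock | None = None,
    seed: int = 0,
) -> SyntheticPanel:
    """Generate a hospital-year panel with known radial inefficiency."""
    if n_hospitals < 1 or not years:
        raise ValueError("need at least one hospital and one year")
    if tech.m != 4 or tech.s != 2:
        raise ValueError("the hospital schema mapping expects 4 inputs and 2 outputs")
    rng = np.random.default_rng(seed)
    n = n_hospitals * len(years)

    lo = np.array([r[0] for r in tech.input_ranges])
    hi = np.array([r[1] for r in tech.input_ranges])
    x_eff = rng.uniform(lo[:, None], hi[:, None], size=(tech.m, n))
    y = _frontier(tech, x_eff)
    theta = _draw_theta(tech, n, rng)

    keys = [(f"H{h+1}", yr) for h in range(n_hospitals) for yr in years]
    if shock is not None:
        in_shock = np.array([yr in shock.years for _, yr in keys])
        y[:, in_shock] *= shock.delta
    x_obs = x_eff / theta

    phys_share = rng.uniform(0.1, 0.6, n)
    nurse_share = rng.uniform(0.0, 0.2, n)
    los = rng.uniform(3.0, 7.0, n)

    records = []
    theta_map = {}
    for j, (hosp, yr) in enumerate(keys):
        beds, phys, nurses, other = x_obs[:, j]
        hosp_n, surg = y[:, j]
        costs = (
            _COST_RATES["physicians"] * phys
            + _COST_RATES["nurses"] * nurses
            + _COST_RATES["other"] * other
            + _COST_RATES["beds"] * beds
        )
        revenue = (
            _REVENUE_RATES["hospitalisations"] * hosp_n
            + _REVENUE_RATES["surgical"] * surg
        )
        occupancy = min(100.0, 100.0 * hosp_n * los[j] / (beds * 365.0))
        records.append(
            HospitalYearRecord(
                hospital_id=hosp,
                year=yr,
                beds=beds,
                physicians_employed=phys * (1 - phys_share[j]),
                physicians_contract=phys * phys_share[j],
                nurses_employed=nurses * (1 - nurse_share[j]),
                nurses_contract=nurses * nurse_share[j],
                other_medical_staff=other,
                hospitalisations=hosp_n,
                surgical_procedures=surg,
                avg_length_of_stay=float(los[j]),
                bed_occupancy=occupancy,
                operating_costs=costs,
                net_revenue=revenue,
            )
        )
        theta_map[(hosp, yr)] = float(theta[j])
    panel = PanelDataset(records, provenance="synthetic")
    return SyntheticPanel(panel=panel, theta_true=theta_map, tech=tech, shock=shock)


def generate_second_stage(
    beta: np.ndarray,
    sigma: float,
    n: int,
    covariate_ranges: tuple[tuple[float, float], ...],
    truncation_point: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Truncated-regression recovery data: (y, X incl. intercept, kept frac).

    Covariates are uniform in their ranges; the latent response is
    X beta + normal error, and only observations above the truncation point
    are retained, exactly the sampling scheme the truncated MLE assumes.
    """
    beta = np.asarray(beta, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if beta.size != len(covariate_ranges) + 1:
        raise ValueError("beta must have one entry per covariate plus intercept")
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [np.ones(n)] + [rng.uniform(lo, hi, n) for lo, hi in covariate_ranges]
    )
    y_star = X @ beta + rng.normal(0.0, sigma, n)
    keep = y_star > truncation_point
    kept_frac = float(keep.mean())
    if kept_frac < 0.01:
        raise DegenerateSampleError(
            f"only {kept_frac:.2%} of latent draws exceed the truncation point"
        )
    return y_star[keep], X[keep], kept_frac
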