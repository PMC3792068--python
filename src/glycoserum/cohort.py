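"""Reference glycan panel and synthetic ulcerative-colitis cohorts.

No patient-level data accompany the study this package operationalizes,
so every pipeline stage is exercised on simulated cohorts with the
statistical structure the analysis assumes:

* a fixed 61-composition reference panel whose structural-class marginals
  match the published summary (5 high-mannose, 6 hybrid, 50 complex of
  which 25/10/15 bi/tri/tetra-antennary, 43 sialylated, 33 fucosylated,
  13 highly sialylated multi-branched, 4 agalactosyl bi-antennary),
  anchored by the named compositions 5402 (m/z 2378), 5410 (1914),
  5200 (1362, panel minimum), 7634 (4157, maximum), 6523 (3341) and
  7624 (4011);
* log-normal glycan abundances with group effects planted in the
  directions the study reports: the fully sialylated bi-antennary 5402
  up in patients, the digalactosyl bi-antennary 5410 down, highly
  sialylated multi-branched and agalactosyl bi-antennary glycans up;
* a single per-patient standard-normal severity latent that jointly
  drives CAI, Mayo endoscopic score, disease extent, steroid-refractory
  status and (weakly) the marker glycans;
* exponential time-to-surgery with a proportional-hazards effect of
  marker-high status and uniform administrative censoring.

The panel membership beyond the six anchored codes is a package fixture
(data, not code) stored under ``data/reference_panel.csv`` and
re-validated against the classifier on every load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import classify
from .core import DEFAULT_MASS_MODEL, GlycanPanel, MassModel
from .stats import marker_ratio
from .survival import dichotomize

__all__ = [
    "reference_panel",
    "EXPECTED_PANEL_COUNTS",
    "CohortConfig",
    "simulate_cohort",
    "null_cohort",
]

#: Published class marginals the packaged panel must reproduce.
EXPECTED_PANEL_COUNTS = {
    "n": 61,
    "high_mannose": 5,
    "hybrid": 6,
    "complex": 50,
    "bi_antennary": 25,
    "tri_antennary": 10,
    "tetra_antennary": 15,
    "sialylated": 43,
    "fucosylated": 33,
    "highly_sialylated_multibranched": 13,
    "agalactosyl_bi": 4,
}

_ANCHORS = {"5200": 1362, "5410": 1914, "5402": 2378, "6523": 3341, "7624": 4011, "7634": 4157}
_MZ_RANGE = (1362.481, 4157.522)

_panel_cache: GlycanPanel | None = None


def reference_panel(model: MassModel = DEFAULT_MASS_MODEL) -> GlycanPanel:
    """Load and validate the packaged 61-glycan reference panel.

    Validation is live — the class marginals are recomputed with the
    current classifier, so a classifier change that breaks the published
    counts fails loudly here.
    """
    global _panel_cache
    if _panel_cache is not None and model is DEFAULT_MASS_MODEL:
        return _panel_cache
    with resources.as_file(
        resources.files("glycoserum").joinpath("data/reference_panel.csv")
    ) as path:
        panel = GlycanPanel.read(path, model=model)
    classify.validate_panel_counts(panel, EXPECTED_PANEL_COUNTS)
    for code, label in _ANCHORS.items():
        if code not in panel or panel.label(code) != label:
            raise ValueError(f"panel anchor {code} (expected label {label}) missing or wrong")
    lo, hi = min(panel.mz), max(panel.mz)
    if abs(lo - _MZ_RANGE[0]) > 2e-3 or abs(hi - _MZ_RANGE[1]) > 2e-3:
        raise ValueError(f"panel m/z range [{lo:.3f}, {hi:.3f}] != expected {_MZ_RANGE}")
    if model is DEFAULT_MASS_MODEL:
        _panel_cache = panel
    return panel


MARKER_UP = "5402"    # fully sialylated bi-antennary, m/z 2378
MARKER_DOWN = "5410"  # digalactosyl core-fucosylated bi-antennary, m/z 1914

#: Codes planted down-regulated in patients besides the marker denominator
#: (neutral/mono-sialylated bi-antennary glycans, the IgG-dominated pool).
_DOWN_CODES = ("5400", "4400", "4410", "6410", "4401", "4411", "4402", "4412", "6401")


def _default_baselines(panel: GlycanPanel) -> dict[str, float]:
    """Baseline log10 abundance (pmol/uL) per glycan.

    Scaled so the per-sample total is a few hundred pmol/uL with the
    marker numerator 5402 the single most abundant serum glycan.
    """
    base = {}
    for comp in panel:
        sc = classify.classify_type(comp)
        if comp.code == MARKER_UP:
            b = 2.0
        elif comp.code == MARKER_DOWN:
            b = 1.0
        elif sc.type == classify.HIGH_MANNOSE:
            b = 0.8
        elif sc.type == classify.HYBRID:
            b = 0.5
        elif sc.antennae == 2:
            b = 0.7
        elif sc.antennae == 3:
            b = 0.6
        else:
            b = 0.5
        base[comp.code] = b
    return base


def _default_effects(panel: GlycanPanel) -> dict[str, float]:
    """Patient-group shift in log10 abundance per glycan."""
    eff = {code: 0.0 for code in panel.codes}
    for comp in panel:
        sc = classify.classify_type(comp)
        if sc.highly_sialylated_multibranched:
            eff[comp.code] = 0.12
        elif sc.agalactosyl_bi:
            eff[comp.code] = 0.10
        elif sc.type == classify.COMPLEX and sc.sialylated:
            eff[comp.code] = 0.06
    for code in _DOWN_CODES:
        eff[code] = -0.06
    eff[MARKER_UP] = 0.22
    eff[MARKER_DOWN] = -0.18
    return eff


def _default_severity_coefs(panel: GlycanPanel) -> dict[str, float]:
    """Coupling of each glycan's log10 abundance to the severity latent."""
    coef = {code: 0.0 for code in panel.codes}
    for comp in panel:
        sc = classify.classify_type(comp)
        if sc.highly_sialylated_multibranched:
            coef[comp.code] = 0.06
        elif sc.type == classify.COMPLEX and sc.sialylated:
            coef[comp.code] = 0.03
    coef[MARKER_UP] = 0.06
    coef[MARKER_DOWN] = -0.04
    # agalactosyl bi-antennary glycans are elevated but, as reported, not
    # activity-correlated: no severity coupling
    for comp in panel:
        if classify.is_agalactosyl_biantennary(comp):
            coef[comp.code] = 0.0
    return coef


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the study's cohort structure.

    ``effects`` / ``severity_coefs`` / ``baselines`` override individual
    glycans on top of the class-based defaults.
    """

    n_uc: int = 75
    n_hlt: int = 75
    seed: int = 0
    log10_sd: float = 0.15
    baselines: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    severity_coefs: dict = field(default_factory=dict)
    # clinical severity couplings
    cai_center: float = 10.0
    cai_slope: float = 4.0
    cai_noise_sd: float = 2.0
    refractory_intercept: float = -1.0
    refractory_slope: float = 1.0
    # survival model
    baseline_hazard: float = 0.008  # per month, marker-low patients
    true_log_hr: float = math.log(4.33)
    censoring: float = 0.4  # target censored fraction in (0, 1)

    def __post_init__(self) -> None:
        if self.n_uc < 2 or self.n_hlt < 2:
            raise ValueError("group sizes must be >= 2")
        if self.log10_sd <= 0 or self.cai_noise_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        if not 0 <= self.censoring < 1:
            raise ValueError("censoring rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")


def _censoring_horizon(cfg: CohortConfig) -> float:
    """Administrative-censoring window giving the target censored fraction.

    With C ~ Uniform(0, t) and T ~ Exp(lam), P(censored) =
    (1 - exp(-lam t)) / (lam t); average that over the marker-low and
    marker-high hazards (half the cohort each) and solve for t.
    """
    lams = (cfg.baseline_hazard, cfg.baseline_hazard * math.exp(cfg.true_log_hr))

    def frac(t: float) -> float:
        return sum((1 - math.exp(-l * t)) / (l * t) for l in lams) / len(lams)

    if cfg.censoring == 0:
        return math.inf
    return float(brentq(lambda t: frac(t) - cfg.censoring, 1e-9, 1e9))


def simulate_cohort(
    config: CohortConfig | None = None,
    panel: GlycanPanel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns ``(abundance, metadata)``: abundance is samples x 61 glycans
    in pmol/uL with composition-code columns; metadata carries group
    (UC/HLT) and, for patients, extent of disease, CAI, Mayo endoscopic
    score, steroid-refractory flag, and time-to-surgery columns
    (``time_months``, ``event``).  Fully reproducible for a fixed config.
    """
    cfg = config or CohortConfig()
    panel = panel or reference_panel()
    rng = np.random.default_rng(cfg.seed)
    codes = list(panel.codes)
    base = {**_default_baselines(panel), **cfg.baselines}
    eff = {**_default_effects(panel), **cfg.effects}
    sev = {**_default_severity_coefs(panel), **cfg.severity_coefs}

    ids = [f"UC{i+1:03d}" for i in range(cfg.n_uc)] + [
        f"HLT{i+1:03d}" for i in range(cfg.n_hlt)
    ]
    n = len(ids)
    is_uc = np.array([s.startswith("UC") for s in ids])

    # severity latent (patients only; controls have no disease process)
    z = np.zeros(n)
    z[is_uc] = rng.standard_normal(cfg.n_uc)

    b = np.array([base[c] for c in codes])
    e = np.array([eff[c] for c in codes])
    s = np.array([sev[c] for c in codes])
    mean_log10 = b[None, :] + np.outer(is_uc.astype(float), e) + np.outer(z * is_uc, s)
    log10_a = mean_log10 + rng.normal(0.0, cfg.log10_sd, size=(n, len(codes)))
    abundance = pd.DataFrame(10.0**log10_a, index=pd.Index(ids, name="sample_id"), columns=codes)

    # clinical strata from the severity latent
    zu = z[is_uc]
    cai = np.clip(
        np.rint(cfg.cai_center + cfg.cai_slope * zu + rng.normal(0, cfg.cai_noise_sd, cfg.n_uc)),
        0, 20,
    ).astype(int)
    mayo_latent = zu + rng.normal(0, 0.6, cfg.n_uc)
    # latent cut points for roughly the published 15/20/40 split of scores 1/2/3
    sd_m = math.sqrt(1 + 0.6**2)
    mayo = np.where(
        mayo_latent > -0.0828 * sd_m,  # ~53% score 3
        3,
        np.where(mayo_latent < -0.8416 * sd_m, 1, 2),  # lowest ~20% score 1
    )
    extent_latent = zu + rng.normal(0, 0.8, cfg.n_uc)
    extent = np.where(extent_latent > -0.665 * math.sqrt(1 + 0.8**2), "total", "left-sided")
    p_refr = 1.0 / (1.0 + np.exp(-(cfg.refractory_intercept + cfg.refractory_slope * zu)))
    refractory = (rng.uniform(size=cfg.n_uc) < p_refr).astype(int)

    metadata = pd.DataFrame(index=abundance.index)
    metadata["group"] = np.where(is_uc, "UC", "HLT")
    metadata["extent"] = pd.array([None] * n, dtype="string")
    metadata.loc[is_uc, "extent"] = extent
    metadata["cai"] = pd.array([pd.NA] * n, dtype="Int64")
    metadata.loc[is_uc, "cai"] = cai
    metadata["mayo"] = pd.array([pd.NA] * n, dtype="Int64")
    metadata.loc[is_uc, "mayo"] = mayo
    metadata["steroid_refractory"] = pd.array([pd.NA] * n, dtype="Int64")
    metadata.loc[is_uc, "steroid_refractory"] = refractory

    # proportional-hazards time to surgery for patients
    ratio = marker_ratio(abundance.loc[is_uc], MARKER_UP, MARKER_DOWN)
    high, _ = dichotomize(ratio, "median")
    lam = cfg.baseline_hazard * np.exp(cfg.true_log_hr * high.to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / lam)
    horizon = _censoring_horizon(cfg)
    if math.isinf(horizon):
        t_cens = np.full(cfg.n_uc, np.inf)
    else:
        t_cens = rng.uniform(0.0, horizon, cfg.n_uc)
    metadata["time_months"] = np.nan
    metadata.loc[is_uc, "time_months"] = np.minimum(t_event, t_cens)
    metadata["event"] = pd.array([pd.NA] * n, dtype="Int64")
    metadata.loc[is_uc, "event"] = (t_event <= t_cens).astype(int)
    return abundance, metadata


def null_cohort(
    config: CohortConfig | None = None,
    panel: GlycanPanel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort with every group effect, severity coupling and hazard effect
    zeroed — the type-I-error / null-calibration harness."""
    cfg = config or CohortConfig()
    panel = panel or reference_panel()
    zeroed = replace(
        cfg,
        effects={c: 0.0 for c in panel.codes},
        severity_coefs={c: 0.0 for c in panel.codes},
        true_log_hr=0.0,
    )
    return simulate_cohort(zeroed, panel=panel)
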