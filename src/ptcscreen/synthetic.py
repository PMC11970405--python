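"""Synthetic wells, images, drug panels and cohorts.

Every downstream stage of the pipeline (segmentation, viability scoring,
Ec calibration, reproducibility QC, clinical concordance) is exercised on
data from this module, which emulates the statistical structure of a PTC
drug test:

* three-stage cluster growth (exponential, stationary/plateau, decline),
  with the plateau lasting 5-25 days;
* wells seeded with 30-50 clusters, photographed at day 0 and day 7;
* multiplicative log-normal measurement noise, so viability ratios stay
  positive and replicate spread is CV-like;
* monotone (Hill-type) dose dependence of the endpoint/baseline area
  ratio -- the analysis itself never fits a dose-response curve, the
  generator only needs a monotone knob;
* validation cohorts with CR/PR, SD and PD classes whose viability
  distributions share a latent sensitivity, so the strength of
  concordance with outcome is a single parameter.

All randomness flows from one integer seed through
:class:`numpy.random.SeedSequence`; per-well substreams are keyed by
(sample, drug, concentration, replicate) so that adding wells never
perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import ndtri

__all__ = [
    "GrowthParams",
    "DrugEffectParams",
    "CohortSpec",
    "simulate_growth_trajectory",
    "render_well_image",
    "sample_cluster_layout",
    "simulate_drug_assay",
    "simulate_cohort",
    "simulate_replicate_matrix",
    "hill_survival",
]

RECIST_CLASSES = ("CR/PR", "SD", "PD")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-s2 / 2.0, math.sqrt(s2), size=size))


def _well_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent substream for one well, indexed by integer key tuple."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Cluster seeding and three-stage growth of one well.

    Defaults describe a healthy PTC well: 30-50 clusters seeded per well
    (default 40), initial equivalent diameters log-normal around ~80 um,
    exponential area growth during the first week, then a plateau of
    5-25 days before decline.

    Parameters
    ----------
    initial_cluster_count
        Clusters seeded per well.
    initial_diameter_log_mean, initial_diameter_log_sd
        Natural-log parameters of the initial equivalent-diameter
        distribution (um).
    exp_rate
        Relative area growth per day in the exponential phase (0.15/day
        doubles total area roughly every 5 days).
    plateau_start_day, plateau_duration_days
        Day the stationary phase begins and how long it lasts.
    decline_rate
        Relative area loss per day after the plateau, in [0, 1).
    measurement_noise_cv
        CV of the multiplicative log-normal error applied independently to
        every area measurement.  The default 0.16 makes the day-7/day-0
        ratio of two independent measurements spread with CV ~= 0.23, the
        between-well replicate spread observed in real PTC panels.
    """

    initial_cluster_count: int = 40
    initial_diameter_log_mean: float = math.log(80.0)
    initial_diameter_log_sd: float = 0.25
    exp_rate: float = 0.15
    plateau_start_day: int = 7
    plateau_duration_days: int = 10
    decline_rate: float = 0.05
    measurement_noise_cv: float = 0.16

    def __post_init__(self):
        vals = (
            self.initial_diameter_log_mean,
            self.initial_diameter_log_sd,
            self.exp_rate,
            self.decline_rate,
            self.measurement_noise_cv,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("growth parameters must be finite")
        if self.initial_cluster_count < 0:
            raise ValueError("initial_cluster_count must be >= 0")
        if self.plateau_duration_days < 0:
            raise ValueError("plateau_duration_days must be >= 0")
        if self.measurement_noise_cv < 0:
            raise ValueError("measurement_noise_cv must be >= 0")
        if not 0.0 <= self.decline_rate < 1.0:
            raise ValueError("decline_rate must be in [0, 1)")


@dataclass(frozen=True)
class DrugEffectParams:
    """Hill-type effect of one drug on the endpoint/baseline area ratio.

    The surviving area fraction at concentration ``c`` (uM) is

        f(c) = 1 - max_kill * c**hill / (c**hill + (potency/sensitivity)**hill)

    ``sensitivity`` is a per-sample multiplier (>1 means the sample is more
    sensitive, shifting the curve to lower concentrations).
    """

    drug_id: str
    potency_um: float
    hill: float = 1.5
    max_kill: float = 0.9
    sensitivity: float = 1.0

    def __post_init__(self):
        if not self.potency_um > 0:
            raise ValueError("potency_um must be > 0")
        if not 0.0 <= self.max_kill <= 1.0:
            raise ValueError("max_kill must be in [0, 1]")
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be > 0")


def hill_survival(conc_um, potency_um: float, hill: float, max_kill: float,
                  sensitivity: float = 1.0):
    """Surviving area fraction under a Hill dose-response (vectorised)."""
    c = np.asarray(conc_um, dtype=float)
    ec = potency_um / sensitivity
    with np.errstate(over="ignore"):
        frac = c**hill / (c**hill + ec**hill)
    return 1.0 - max_kill * frac


@dataclass(frozen=True)
class CohortSpec:
    """Composition and viability model of a synthetic validation cohort.

    One row is one treatment (a patient may contribute several).  Mean
    viability is log-normal within each RECIST class; class locations are
    given on the natural-log scale so draws are automatically positive.
    The gap between class locations relative to ``log_sd`` is the single
    knob controlling concordance strength.

    The default emulates the published validation cohort: 60 treatments
    split 8 CR/PR, 40 SD, 12 PD, with 33/60 prospective.
    """

    n_crpr: int = 8
    n_sd: int = 40
    n_pd: int = 12
    crpr_log_mean: float = math.log(0.40)
    sd_log_mean: float = math.log(0.85)
    pd_log_mean: float = math.log(1.30)
    log_sd: float = 0.35
    prospective_fraction: float = 33.0 / 60.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_crpr, self.n_sd, self.n_pd) < 0:
            raise ValueError("class counts must be >= 0")
        if self.n_crpr + self.n_sd + self.n_pd == 0:
            raise ValueError("at least one class count must be nonzero")
        if not 0.0 <= self.prospective_fraction <= 1.0:
            raise ValueError("prospective_fraction must be in [0, 1]")

    @classmethod
    def perfect_separation(cls, n_crpr: int = 8, n_sd: int = 40, n_pd: int = 12,
                           seed: int = 0) -> "CohortSpec":
        """Spec whose draws cannot overlap across the 0.7 cutoff.

        CR/PR viabilities concentrate far below 0.7 and SD/PD far above, so
        downstream accuracy and AUC are forced to 1 by construction.
        """
        return cls(
            n_crpr=n_crpr, n_sd=n_sd, n_pd=n_pd,
            crpr_log_mean=math.log(0.25),
            sd_log_mean=math.log(1.10),
            pd_log_mean=math.log(1.60),
            log_sd=0.05,
            seed=seed,
        )

    @classmethod
    def for_target_auc(cls, auc: float, n_crpr: int = 8, n_sd: int = 40,
                       n_pd: int = 12, log_sd: float = 0.35,
                       seed: int = 0) -> "CohortSpec":
        """Spec whose CR/PR vs SD+PD population AUC equals ``auc``.

        Under the binormal model on log viability with equal spread ``s``
        in both groups, AUC = Phi(delta / (s * sqrt(2))); solving for the
        location gap gives delta = sqrt(2) * s * Phi^-1(auc).  SD and PD
        share one location so the two-group AUC is exact.
        """
        if not 0.0 < auc < 1.0:
            raise ValueError("target auc must be in (0, 1)")
        delta = math.sqrt(2.0) * log_sd * float(ndtri(auc))
        base = math.log(0.45)
        return cls(
            n_crpr=n_crpr, n_sd=n_sd, n_pd=n_pd,
            crpr_log_mean=base,
            sd_log_mean=base + delta,
            pd_log_mean=base + delta,
            log_sd=log_sd,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# growth trajectories
# ---------------------------------------------------------------------------


def _initial_cluster_diameters(params: GrowthParams, rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.normal(params.initial_diameter_log_mean,
                             params.initial_diameter_log_sd,
                             size=params.initial_cluster_count))


def _initial_total_area(params: GrowthParams, rng: np.random.Generator) -> float:
    d = _initial_cluster_diameters(params, rng)
    return float(np.sum(np.pi * (d / 2.0) ** 2))


def _growth_multiplier(params: GrowthParams, day: int) -> float:
    """Noise-free total-area multiplier for the transition into ``day``."""
    if day <= params.plateau_start_day:
        return 1.0 + params.exp_rate
    if day <= params.plateau_start_day + params.plateau_duration_days:
        return 1.0
    return 1.0 - params.decline_rate


def noise_free_area(params: GrowthParams, day: int, initial_area: float) -> float:
    """Total area at ``day`` on the piecewise exponential/plateau/decline path."""
    a = initial_area
    for t in range(1, day + 1):
        a *= _growth_multiplier(params, t)
    return a


def simulate_growth_trajectory(params: GrowthParams, days: int,
                               seed: int | None = None,
                               initial_area: float | None = None) -> np.ndarray:
    """Daily total cluster area (um^2) for days 0..``days``.

    The noise-free path compounds ``exp_rate`` daily until
    ``plateau_start_day``, stays flat for ``plateau_duration_days``, then
    decays at ``decline_rate``; each day's measurement is perturbed by an
    independent multiplicative log-normal factor with CV
    ``measurement_noise_cv``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    if initial_area is None:
        initial_area = _initial_total_area(params, rng)
    clean = np.empty(days + 1)
    clean[0] = initial_area
    for t in range(1, days + 1):
        clean[t] = clean[t - 1] * _growth_multiplier(params, t)
    noise = _lognormal_factor(rng, params.measurement_noise_cv, size=days + 1)
    return clean * noise


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def sample_cluster_layout(n_clusters: int, diameters_um: Sequence[float],
                          image_shape: tuple[int, int], pixel_size_um: float,
                          rng: np.random.Generator,
                          max_tries: int = 2000) -> list[tuple[float, float, float]]:
    """Place ``n_clusters`` non-overlapping disks inside the field of view.

    Returns (row_px, col_px, diameter_um) triples.  Rejection sampling;
    raises if the well is too crowded to place all disks.
    """
    h, w = image_shape
    placed: list[tuple[float, float, float]] = []
    for i in range(n_clusters):
        r_px = diameters_um[i] / 2.0 / pixel_size_um
        ok = False
        for _ in range(max_tries):
            row = rng.uniform(r_px + 1, h - r_px - 1)
            col = rng.uniform(r_px + 1, w - r_px - 1)
            if all((row - pr) ** 2 + (col - pc) ** 2
                   > (r_px + pd_ / 2.0 / pixel_size_um + 2) ** 2
                   for pr, pc, pd_ in placed):
                placed.append((row, col, float(diameters_um[i])))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place cluster {i} of {n_clusters} without overlap; "
                "reduce count or diameters"
            )
    return placed


def render_well_image(clusters: Sequence[tuple[float, float, float]],
                      pixel_size_um: float = 1.0,
                      image_shape: tuple[int, int] = (512, 512),
                      background_level: float = 200.0,
                      cluster_level: float = 80.0,
                      noise_sd: float = 0.0,
                      blur_sigma_px: float = 0.0,
                      seed: int | None = None) -> tuple[np.ndarray, dict]:
    """Render clusters as dark disks on a bright background.

    ``clusters`` holds (row_px, col_px, diameter_um) triples; centers may be
    sub-pixel.  Gaussian read noise (``noise_sd``) and optional blur emulate
    brightfield optics.  The returned metadata carries the analytic
    ground-truth area pi*(d/2)^2 of each disk, the quantity segmentation is
    later judged against.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    h, w = image_shape
    img = np.full((h, w), background_level, dtype=float)
    rows, cols = np.mgrid[0:h, 0:w]
    meta_clusters = []
    for row, col, diam_um in clusters:
        r_px = diam_um / 2.0 / pixel_size_um
        mask = (rows - row) ** 2 + (cols - col) ** 2 <= r_px**2
        img[mask] = cluster_level
        meta_clusters.append({
            "center_px": (float(row), float(col)),
            "diameter_um": float(diam_um),
            "area_um2": float(np.pi * (diam_um / 2.0) ** 2),
        })
    if blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, blur_sigma_px)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    meta = {
        "pixel_size_um": float(pixel_size_um),
        "background_level": float(background_level),
        "cluster_level": float(cluster_level),
        "clusters": meta_clusters,
        "total_area_um2": float(sum(c["area_um2"] for c in meta_clusters)),
    }
    return img, meta


# ---------------------------------------------------------------------------
# drug assays
# ---------------------------------------------------------------------------

NEGATIVE_CONTROL = "NC"


def simulate_drug_assay(growth: GrowthParams,
                        effects: Sequence[DrugEffectParams],
                        concentrations: Sequence[float],
                        replicates: int = 3,
                        seed: int = 0,
                        sample_id: str = "S1",
                        sample_index: int = 0,
                        t0_day: int = 0,
                        t1_day: int = 7,
                        include_negative_control: bool = True) -> pd.DataFrame:
    """Simulate one sample's drug test as a table of replicate wells.

    Each (drug, concentration, replicate) well carries baseline and endpoint
    total areas ``S_t0``/``S_t1`` whose noise-free ratio equals the product
    of the negative-control growth ratio and the Hill survival fraction;
    that product is stored as ``true_viability`` for recovery tests.
    Negative-control wells (concentration NaN, drug "NC") carry the bare
    growth ratio.

    Replication defaults to 3 wells per drug-sample pair; photographs at
    day 0 and day 7.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list must be non-empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")

    base_rng = _well_rng(seed, sample_index, 0, 0, 0)
    a0 = _initial_total_area(growth, base_rng) if growth.initial_cluster_count else 1e5
    g0 = noise_free_area(growth, t0_day, a0)
    g1 = noise_free_area(growth, t1_day, a0)
    growth_ratio = g1 / g0

    rows = []

    def _well(drug_id, conc_val, rep, viability, drug_idx, conc_idx):
        rng = _well_rng(seed, sample_index, drug_idx, conc_idx, rep)
        s_t0 = g0 * _lognormal_factor(rng, growth.measurement_noise_cv)
        s_t1 = s_t0 * viability * _lognormal_factor(rng, growth.measurement_noise_cv)
        rows.append({
            "sample_id": sample_id,
            "drug_id": drug_id,
            "concentration_um": conc_val,
            "replicate": rep,
            "S_t0_um2": s_t0,
            "S_t1_um2": s_t1,
            "true_viability": viability,
        })

    if include_negative_control:
        for rep in range(1, replicates + 1):
            _well(NEGATIVE_CONTROL, np.nan, rep, growth_ratio, 0, 0)

    for d_idx, eff in enumerate(effects, start=1):
        surv = hill_survival(conc, eff.potency_um, eff.hill, eff.max_kill,
                             eff.sensitivity)
        for c_idx, (c, f) in enumerate(zip(conc, surv), start=1):
            v = growth_ratio * float(f)
            for rep in range(1, replicates + 1):
                _well(eff.drug_id, float(c), rep, v, d_idx, c_idx)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts and replicate matrices
# ---------------------------------------------------------------------------


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One treatment per row: viability, RECIST class, prospective flag.

    Columns: patient_id, sample_id, regimen, pA, recist, prospective.
    """
    rng = np.random.default_rng(spec.seed)
    counts = {"CR/PR": spec.n_crpr, "SD": spec.n_sd, "PD": spec.n_pd}
    locs = {"CR/PR": spec.crpr_log_mean, "SD": spec.sd_log_mean,
            "PD": spec.pd_log_mean}
    rows = []
    i = 0
    for cls in RECIST_CLASSES:
        via = np.exp(rng.normal(locs[cls], spec.log_sd, size=counts[cls]))
        for v in via:
            i += 1
            rows.append({
                "patient_id": f"PT-{i:03d}",
                "sample_id": f"SMP-{i:03d}",
                "regimen": f"regimen-{i:03d}",
                "pA": float(v),
                "recist": cls,
                "prospective": bool(rng.random() < spec.prospective_fraction),
            })
    return pd.DataFrame(rows)


def _c4(n: int) -> float:
    """E[sample SD] / population SD for n normal draws (small-sample bias)."""
    from scipy.special import gammaln

    return math.sqrt(2.0 / (n - 1)) * math.exp(gammaln(n / 2) - gammaln((n - 1) / 2))


def simulate_replicate_matrix(n_pairs: int = 337, n_replicates: int = 3,
                              noise_cv: float = 0.23,
                              row_log_sd: float = 0.6,
                              row_log_mean: float = math.log(0.7),
                              seed: int = 0) -> pd.DataFrame:
    """Replicate viability matrix for reproducibility QC.

    Rows are drug-sample pairs (337 in the real panel), columns replicate
    wells (3 per pair).  Each row has a latent true viability drawn
    log-normally across rows; replicates scatter around it with
    multiplicative log-normal noise.

    ``noise_cv`` is the *expected observed* replicate CV, i.e. the mean of
    per-row sample CVs (SD/mean over ``n_replicates`` wells) -- the
    quantity reproducibility reports actually summarize (0.23 in the real
    panel).  Because the sample SD of n draws underestimates the
    population SD by the factor c4(n) (~0.886 at n = 3), the generator
    inflates the underlying population CV by 1/c4 so the observed mean CV
    matches the knob.
    """
    if n_pairs < 1 or n_replicates < 2:
        raise ValueError("need >= 1 row and >= 2 replicate columns")
    rng = np.random.default_rng(seed)
    truth = np.exp(rng.normal(row_log_mean, row_log_sd, size=n_pairs))
    noise = _lognormal_factor(rng, noise_cv / _c4(n_replicates),
                              size=(n_pairs, n_replicates))
    mat = truth[:, None] * noise
    df = pd.DataFrame(mat, columns=[f"replicate_{j + 1}" for j in range(n_replicates)])
    df.insert(0, "pair_id", [f"pair-{i + 1:04d}" for i in range(n_pairs)])
    df["true_viability"] = truth
    return df
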