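"""Synthetic cohorts with the statistical structure the similarity analysis assumes.

The generator emulates a longitudinal ageing cohort stratified by amyloid
status: a normative reference group whose regional cortical thickness carries
a structured inter-regional correlation matrix plus demographic covariate
effects, and two target groups (incident / elevated amyloid-positive) whose
thickness is drawn from a covariance with planted edge perturbations.
Cognitive trajectories decline in proportion to each subject's similarity
deviation, fluid biomarkers are log-normal with an upward group shift, and
conversion labels follow a logistic model on the deviation score.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

CYTOARCH_CLASSES = ("PMC", "PSC", "SSC", "AC1", "AC2", "LIMB", "INS")

#: raw cognitive tests emitted by the generator, with (mean, sd) on the raw
#: scale and whether a higher raw score means worse performance (inverted
#: downstream).  Magnitudes follow typical cognitively-normal cohorts.
COGNITIVE_TESTS: dict[str, tuple[float, float, bool]] = {
    "mmse": (29.0, 1.0, False),
    "adasq4": (2.0, 1.5, True),
    "lmdrt": (14.0, 4.0, False),
    "tmt_a": (30.0, 9.0, True),
    "tmt_b": (70.0, 25.0, True),
    "bnt": (29.0, 2.0, False),
    "clock": (5.0, 0.5, False),
    "adl": (0.5, 0.3, False),
}

#: tests inverted before z-scoring so that higher always means better
DEFAULT_INVERT = ("adasq4", "tmt_a", "tmt_b")

#: baseline fluid biomarkers: name -> (median pg/mL, log-scale sd)
BIOMARKERS: dict[str, tuple[float, float]] = {
    "csf_ptau181": (12.0, 0.40),
    "csf_ttau": (30.0, 0.40),
    "plasma_ptau181": (17.0, 0.45),
    "plasma_nfl": (196.0, 0.35),
}

GROUPS = ("stable_negative", "incident_positive", "elevated_positive")


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


def dk68_region_names() -> list[str]:
    """Ordered 68-name Desikan-Killiany list (lh then rh, alphabetical bases)."""
    path = resources.files("brainsim.data") / "dk68_von_economo.csv"
    bases = pd.read_csv(str(path))["region"].tolist()
    return [f"{hemi}_{b}" for hemi in ("lh", "rh") for b in bases]


def region_names(n_regions: int) -> list[str]:
    if n_regions == 68:
        return dk68_region_names()
    width = len(str(n_regions))
    return [f"region_{i:0{width}d}" for i in range(n_regions)]


#: relative sizes of the seven cytoarchitectural classes in the 34-name
#: Desikan-Killiany base list (PMC, PSC, SSC, AC1, AC2, LIMB, INS)
CLASS_FRACTIONS = np.array([2, 3, 4, 13, 4, 7, 1]) / 34.0


def cytoarch_block_sizes(n_regions: int) -> np.ndarray:
    """Community sizes proportional to the cytoarchitectural class sizes
    (largest-remainder rounding, every class at least one region)."""
    raw = CLASS_FRACTIONS * n_regions
    sizes = np.maximum(np.floor(raw).astype(int), 1)
    remainder = raw - np.floor(raw)
    while sizes.sum() < n_regions:
        i = int(np.argmax(np.where(sizes >= 1, remainder, -1)))
        sizes[i] += 1
        remainder[i] = -1
    while sizes.sum() > n_regions:
        i = int(np.argmax(sizes))
        sizes[i] -= 1
    return sizes


def block_correlation(
    n_regions: int,
    within: float = 0.5,
    between: float = 0.15,
) -> np.ndarray:
    """Block (community) structured correlation matrix with unit diagonal.

    The seven blocks mirror the cytoarchitectural classes (with realistic
    relative sizes) so that planted perturbations can be localized to
    biologically coherent communities.
    """
    sizes = cytoarch_block_sizes(n_regions)
    labels = np.repeat(np.arange(7), sizes)
    same = labels[:, None] == labels[None, :]
    mat = np.where(same, within, between)
    np.fill_diagonal(mat, 1.0)
    return mat


def nearest_psd_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by eigenvalue clipping,
    then rescale to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def _is_psd(mat: np.ndarray, tol: float = -1e-10) -> bool:
    return bool(np.linalg.eigvalsh((mat + mat.T) / 2.0).min() >= tol)


@dataclass
class SimConfig:
    """Generating parameters for one synthetic cohort.

    Group sizes default to the ADNI-like configuration (114 reference, 26
    incident, 45 elevated amyloid-positive) with 68 atlas regions and three
    annual visits (two years of follow-up).
    """

    n_reference: int = 114
    n_incident: int = 26
    n_elevated: int = 45
    n_regions: int = 68
    n_visits: int = 3
    visit_spacing_years: float = 1.0
    base_covariance: np.ndarray | None = None
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {"age": -0.008, "sex": 0.05, "education": 0.0}
    )
    perturbed_edges: list[tuple[int, int]] | None = None
    perturbation_strength: float = 0.4
    elevated_multiplier: float = 1.5
    interaction_beta: float = -0.4
    random_intercept_sd: float = 0.5
    residual_sd: float = 0.25
    time_slope: float = -0.05
    biomarker_group_shift: float = 0.3
    conversion_betas: tuple[float, ...] = (-1.5, 8.0)
    deviation_mode: str = "network"  # "network" | "product" | "latent"
    thickness_mean: float = 2.5
    thickness_sd: float = 0.12
    measurement_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_covariance is None:
            self.base_covariance = block_correlation(self.n_regions)
        else:
            self.base_covariance = np.asarray(self.base_covariance, dtype=float)
        if self.perturbed_edges is None:
            self.perturbed_edges = default_perturbed_edges(self.n_regions)
        self.validate()

    def validate(self) -> None:
        cov = self.base_covariance
        if cov.shape != (self.n_regions, self.n_regions):
            raise ConfigurationError(
                f"base_covariance shape {cov.shape} does not match "
                f"n_regions={self.n_regions}"
            )
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ConfigurationError("base_covariance must be symmetric")
        if not np.allclose(np.diag(cov), 1.0, atol=1e-12):
            raise ConfigurationError("base_covariance must have unit diagonal")
        if not _is_psd(cov, tol=-1e-8):
            raise ConfigurationError("base_covariance is not positive semidefinite")
        if self.n_visits < 2:
            raise ConfigurationError("n_visits must be >= 2")
        if not (0.0 <= self.perturbation_strength < 1.0):
            raise ConfigurationError("perturbation_strength must lie in [0, 1)")
        for j, k in self.perturbed_edges:
            if not (0 <= j < self.n_regions and 0 <= k < self.n_regions and j != k):
                raise ConfigurationError(f"invalid perturbed edge ({j}, {k})")
        if self.deviation_mode not in ("network", "product", "latent"):
            raise ConfigurationError(
                "deviation_mode must be 'network', 'product' or 'latent'"
            )
        # the planted shift must stay repairable at the strongest multiplier
        perturbed_covariance(self, exposure=1.0, multiplier=self.elevated_multiplier)

    @property
    def region_names(self) -> list[str]:
        return region_names(self.n_regions)

    @property
    def thickness_columns(self) -> list[str]:
        return [f"thick_{r}" for r in self.region_names]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["base_covariance"] = np.asarray(d["base_covariance"]).tolist()
        d["perturbed_edges"] = [list(e) for e in d["perturbed_edges"]]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["base_covariance"] = np.asarray(d["base_covariance"], dtype=float)
        d["perturbed_edges"] = [tuple(e) for e in d["perturbed_edges"]]
        d["conversion_betas"] = tuple(d["conversion_betas"])
        return cls(**d)


def default_perturbed_edges(n_regions: int, n_edges: int = 5) -> list[tuple[int, int]]:
    """Planted edges: a star around a hub in the fourth community block.

    A hub topology concentrates the perturbation on one region so that the
    affected edges co-vary, which mimics focal disconnection of an
    association-cortex hub and keeps the planted ground truth recoverable.
    The hub sits in the AC1 community (the largest cytoarchitectural class).
    """
    sizes = cytoarch_block_sizes(n_regions)
    start = int(sizes[:3].sum())  # first region of the AC1 block
    block = range(start, start + int(sizes[3]))
    hub = start
    spokes = [r for r in block if r != hub][: n_edges]
    if len(spokes) < n_edges:  # tiny atlases: extend into the next block
        extra = [r for r in range(n_regions) if r != hub and r not in spokes]
        spokes += extra[: n_edges - len(spokes)]
    return [(hub, s) for s in spokes]


def perturbed_covariance(
    cfg: SimConfig, exposure: float, multiplier: float, repair_tol: float = 0.15
) -> np.ndarray:
    """Base correlation with planted edges shifted by ``-strength*exposure*multiplier``,
    re-projected to the nearest PSD correlation matrix."""
    shift = cfg.perturbation_strength * exposure * multiplier
    if shift == 0.0:
        return cfg.base_covariance.copy()
    target = cfg.base_covariance.copy()
    for j, k in cfg.perturbed_edges:
        val = np.clip(target[j, k] - shift, -0.99, 0.99)
        target[j, k] = target[k, j] = val
    repaired = nearest_psd_correlation(target)
    worst = max(abs(repaired[j, k] - target[j, k]) for j, k in cfg.perturbed_edges)
    if worst > repair_tol:
        raise ConfigurationError(
            f"perturbation breaks positive semidefiniteness beyond repair "
            f"tolerance (planted-edge distortion {worst:.3f} > {repair_tol})"
        )
    return repaired


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, cfg.seed])


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    def truncated(mean, sd, lo, hi, size):
        out = rng.normal(mean, sd, size)
        while True:
            bad = (out < lo) | (out > hi)
            if not bad.any():
                return out
            out[bad] = rng.normal(mean, sd, bad.sum())

    return pd.DataFrame(
        {
            "age": np.round(truncated(71.0, 8.0, 55.0, 95.0, n), 1),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": np.round(truncated(16.0, 3.0, 8.0, 22.0, n), 0),
            "tiv": rng.normal(1.5e6, 1.5e5, n),
        }
    )


def _subject_rows(
    cfg: SimConfig,
    rng: np.random.Generator,
    subject_ids: Sequence[str],
    group: str,
    exposures: np.ndarray,
    multiplier: float,
) -> pd.DataFrame:
    """Simulate thickness / volumes for a set of subjects across visits."""
    n = len(subject_ids)
    covs = _draw_covariates(rng, n)
    betas = cfg.covariate_betas
    base = cfg.base_covariance
    times = np.arange(cfg.n_visits) * cfg.visit_spacing_years

    rows = []
    for i, sid in enumerate(subject_ids):
        cov_i = perturbed_covariance(cfg, float(exposures[i]), multiplier)
        chol = np.linalg.cholesky(cov_i + 1e-10 * np.eye(cfg.n_regions))
        latent = chol @ rng.standard_normal(cfg.n_regions)
        # realized deviation: how far the subject's planted-edge products sit
        # below the normative correlations (positive = more disrupted)
        prods = np.array([base[j, k] - latent[j] * latent[k] for j, k in cfg.perturbed_edges])
        if cfg.deviation_mode == "latent":
            deviation = float(exposures[i] * multiplier * cfg.perturbation_strength)
        else:
            # provisional product-based deviation; in "network" mode it is
            # replaced by the measured similarity deviation once the full
            # cohort (with its reference group) is available
            deviation = float(prods.mean())
        # competing markers carry a weak share of the disease process:
        # focal thinning at the perturbed regions and mild volume loss
        hippo = rng.normal(7500.0, 600.0) - 150.0 * deviation
        vent = float(np.exp(rng.normal(np.log(3.0e4), 0.3))) * (1 + 0.05 * deviation)
        gm = rng.normal(6.0e5, 4.0e4) - 8000.0 * deviation
        atrophy = np.zeros(cfg.n_regions)
        for j, k in cfg.perturbed_edges:
            atrophy[j] += 0.5
            atrophy[k] += 0.5
        atrophy = 0.02 * deviation * np.minimum(atrophy, 1.0)
        for t in times:
            age_t = covs.loc[i, "age"] + t
            effect = (
                betas.get("age", 0.0) * (age_t - 71.0)
                + betas.get("sex", 0.0) * covs.loc[i, "sex"]
                + betas.get("education", 0.0) * (covs.loc[i, "education"] - 16.0)
            )
            thick = (
                cfg.thickness_mean
                + effect
                + cfg.thickness_sd * latent
                - atrophy
                + cfg.measurement_sd * rng.standard_normal(cfg.n_regions)
            )
            row = {
                "subject_id": sid,
                "group": group,
                "visit_time": float(t),
                "age": float(age_t),
                "sex": float(covs.loc[i, "sex"]),
                "education": float(covs.loc[i, "education"]),
                "tiv": float(covs.loc[i, "tiv"]),
                "deviation": deviation,
                "hippocampal_volume": float(hippo - 15.0 * t + rng.normal(0, 40.0)),
                "ventricular_volume": float(vent * (1 + 0.02 * t) + rng.normal(0, 400.0)),
                "gray_matter_volume": float(gm - 800.0 * t + rng.normal(0, 2000.0)),
                "cognition_offset_months": float(rng.uniform(-2.5, 2.5)),
                "pet_offset_months": float(rng.uniform(-2.5, 2.5)),
            }
            row.update(dict(zip(cfg.thickness_columns, thick)))
            rows.append(row)
    return pd.DataFrame(rows)


def generate_reference_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Amyloid-negative normative subjects drawn from the base covariance."""
    rng = _rng(cfg, 1)
    ids = [f"REF{i:04d}" for i in range(cfg.n_reference)]
    exposures = np.zeros(cfg.n_reference)
    return _subject_rows(cfg, rng, ids, "stable_negative", exposures, 0.0)


def generate_target_subjects(cfg: SimConfig) -> pd.DataFrame:
    """Incident and elevated amyloid-positive subjects with planted covariance
    perturbations (elevated group gets the larger shift multiplier)."""
    rng = _rng(cfg, 2)
    inc_ids = [f"INC{i:04d}" for i in range(cfg.n_incident)]
    ele_ids = [f"ELE{i:04d}" for i in range(cfg.n_elevated)]
    inc_exp = rng.uniform(0.5, 1.0, cfg.n_incident)
    ele_exp = rng.uniform(0.5, 1.0, cfg.n_elevated)
    inc = _subject_rows(cfg, rng, inc_ids, "incident_positive", inc_exp, 1.0)
    ele = _subject_rows(cfg, rng, ele_ids, "elevated_positive", ele_exp, cfg.elevated_multiplier)
    return pd.concat([inc, ele], ignore_index=True)


def compute_network_deviation(cohort: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Replace the deviation column with the measured similarity deviation.

    Builds the reference partial-correlation network from the cohort's own
    amyloid-negative group and, for every target subject, the perturbation-
    based individual network at baseline; the deviation score is the negated
    mean z value over the planted edges (positive = planted edges weakened).
    Reference subjects keep deviation 0 (they define the norm).
    """
    from . import network_construction as nc

    out = cohort.copy()
    reference = out[out["group"] == "stable_negative"]
    targets = out[out["group"] != "stable_negative"]
    if reference.empty or targets.empty:
        raise ConfigurationError(
            "network deviation mode needs both reference and target subjects"
        )
    ref_net = nc.build_reference_network(reference)
    name_to_idx = {r: i for i, r in enumerate(ref_net.region_names)}
    planted_idx = [
        (name_to_idx[cfg.region_names[j]], name_to_idx[cfg.region_names[k]])
        for j, k in cfg.perturbed_edges
    ]
    base_rows = targets.sort_values("visit_time").drop_duplicates("subject_id")
    dev = {s: 0.0 for s in reference["subject_id"].unique()}
    for _, row in base_rows.iterrows():
        net = nc.build_individual_network(row, reference, ref_net)
        dev[row["subject_id"]] = -float(
            np.mean([net.z_matrix[j, k] for j, k in planted_idx])
        )
    out["deviation"] = out["subject_id"].map(dev)
    return out


def generate_longitudinal_cognition(cohort: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Attach raw cognitive scores whose slopes depend on the deviation score.

    Latent trajectory per subject and test:
    ``y_it = b_i + time_slope * t + interaction_beta * deviation_i * t
    + covariate terms + eps_it`` with ``b_i ~ N(0, random_intercept_sd^2)``
    and ``eps ~ N(0, residual_sd^2)``; the latent score is mapped onto each
    test's raw scale (negated for tests where higher raw = worse).
    """
    rng = _rng(cfg, 3)
    out = cohort.copy()
    if cfg.deviation_mode == "network" and (out["group"] == "stable_negative").any():
        out = compute_network_deviation(out, cfg)
    subjects = out["subject_id"].unique()
    sub_idx = {s: i for i, s in enumerate(subjects)}
    for test, (mean, sd, higher_is_worse) in COGNITIVE_TESTS.items():
        b = rng.normal(0.0, cfg.random_intercept_sd, len(subjects))
        eps = rng.normal(0.0, cfg.residual_sd, len(out))
        t = out["visit_time"].to_numpy()
        dev = out["deviation"].to_numpy()
        latent = (
            b[[sub_idx[s] for s in out["subject_id"]]]
            + cfg.time_slope * t
            + cfg.interaction_beta * dev * t
            - 0.01 * (out["age"].to_numpy() - 71.0)
            + 0.02 * (out["education"].to_numpy() - 16.0)
            + eps
        )
        sign = -1.0 if higher_is_worse else 1.0
        out[test] = mean + sign * sd * latent
    return out


def generate_biomarkers(cohort: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Baseline log-normal fluid biomarkers, shifted upward (log scale) in the
    amyloid-positive groups; recorded on baseline rows only."""
    rng = _rng(cfg, 4)
    out = cohort.copy()
    baseline = out.groupby("subject_id")["visit_time"].transform("min") == out["visit_time"]
    positive = out["group"].isin(["incident_positive", "elevated_positive"])
    dev = out.drop_duplicates("subject_id").set_index("subject_id")["deviation"]
    for name, (median, log_sd) in BIOMARKERS.items():
        per_subject = {
            s: float(np.exp(rng.normal(np.log(median), log_sd) + 0.25 * dev[s]))
            for s in out["subject_id"].unique()
        }
        vals = out["subject_id"].map(per_subject)
        vals = vals * np.exp(np.where(positive, cfg.biomarker_group_shift, 0.0))
        out[name] = np.where(baseline, vals, np.nan)
    return out


def generate_conversion_labels(cohort: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Bernoulli conversion labels from a logistic model on the deviation score."""
    rng = _rng(cfg, 5)
    out = cohort.copy()
    per_subject = out.drop_duplicates("subject_id")[["subject_id", "deviation"]]
    design = np.column_stack(
        [np.ones(len(per_subject)), per_subject["deviation"].to_numpy()]
    )
    betas = np.asarray(cfg.conversion_betas, dtype=float)
    if betas.shape[0] != design.shape[1]:
        raise ConfigurationError(
            f"conversion_betas has length {betas.shape[0]}, expected {design.shape[1]}"
        )
    prob = expit(design @ betas)
    labels = (rng.uniform(size=len(per_subject)) < prob).astype(int)
    mapping = dict(zip(per_subject["subject_id"], labels))
    out["converted"] = out["subject_id"].map(mapping)
    return out


def generate_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Full cohort: reference + targets with cognition, biomarkers, labels."""
    ref = generate_reference_cohort(cfg)
    targets = generate_target_subjects(cfg)
    cohort = pd.concat([ref, targets], ignore_index=True)
    cohort = generate_longitudinal_cognition(cohort, cfg)
    cohort = generate_biomarkers(cohort, cfg)
    cohort = generate_conversion_labels(cohort, cfg)
    return cohort


def save_cohort(cohort: pd.DataFrame, cfg: SimConfig, csv_path) -> None:
    """Tidy CSV (one row per subject-visit) with a JSON sidecar of the config."""
    cohort.to_csv(csv_path, index=False)
    sidecar = str(csv_path).removesuffix(".csv") + "_config.json"
    with open(sidecar, "w") as fh:
        fh.write(cfg.to_json())


def load_cohort(csv_path) -> tuple[pd.DataFrame, SimConfig | None]:
    cohort = pd.read_csv(csv_path)
    sidecar = str(csv_path).removesuffix(".csv") + "_config.json"
    cfg = None
    try:
        with open(sidecar) as fh:
            cfg = SimConfig.from_json(fh.read())
    except FileNotFoundError:
        pass
    return cohort, cfg
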