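"""Reference structural covariance network, perturbation-based individual
similarity networks, and the reference-size stability analysis.

The reference network is the matrix of partial Pearson correlations between
regional cortical thickness values across the normative group, controlling
for demographic covariates (age, sex, education).  Partialling is done by
residualizing each region on the covariates and correlating the residuals,
which is exactly the textbook partial correlation for those covariates.

An individual similarity network is obtained by appending one subject-visit
to the normative data, recomputing the partial-correlation network with the
same covariate adjustment, subtracting the reference, and z-scoring the
difference over the off-diagonal upper-triangle edges within the subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass
class ReferenceNetwork:
    matrix: np.ndarray
    n_subjects: int
    covariates_used: tuple[str, ...]
    region_names: list[str]

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.array_equal(m, m.T):
            raise ValueError("reference network must be exactly symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("reference network must have unit diagonal")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if np.any(np.abs(off) >= 1.0 - 1e-10):
            bad = np.argwhere(np.abs(m) >= 1.0 - 1e-10)
            bad = [tuple(b) for b in bad if b[0] != b[1]]
            raise ValueError(
                f"off-diagonal correlations at machine |r|=1 (duplicate or "
                f"collinear regions?): {bad[:4]}"
            )

    def edge_vector(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.region_names, columns=self.region_names)


@dataclass
class IndividualSimilarityNetwork:
    subject_id: str
    visit_time: float
    z_matrix: np.ndarray
    raw_difference: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def edge_vector(self, which: str = "z") -> np.ndarray:
        mat = self.z_matrix if which == "z" else self.raw_difference
        iu = np.triu_indices(mat.shape[0], k=1)
        return mat[iu]


@dataclass
class StabilityCurve:
    sample_sizes: np.ndarray
    mean_icc: np.ndarray
    n_reps: int
    reliability_threshold: float
    min_reliable_n: int | None


def edge_names(regions: list[str]) -> list[str]:
    iu = np.triu_indices(len(regions), k=1)
    return [f"{regions[i]}|{regions[j]}" for i, j in zip(*iu)]


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of each column of ``values`` on
    ``[intercept, covariates]``; zero-variance covariate columns are dropped.

    Raises on rank deficiency, naming the collinear columns.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if np.isnan(values).any():
        raise ValueError("values contain missing entries")
    design = np.ones((n, 1))
    kept: list[int] = []
    if covariates is not None and np.size(covariates):
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if np.isnan(covariates).any():
            raise ValueError("covariates contain missing entries")
        kept = [j for j in range(covariates.shape[1]) if covariates[:, j].std() > 0]
        if kept:
            design = np.column_stack([design, covariates[:, kept]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(design[:, 1:], rowvar=False)
        pairs = [
            (kept[a], kept[b])
            for a in range(corr.shape[0])
            for b in range(a + 1, corr.shape[0])
            if abs(corr[a, b]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {pairs}")
    if design.shape[1] >= n - 1:
        raise ValueError("too few rows to residualize on this many covariates")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def _partial_corr_matrix(
    values: np.ndarray, covariates: np.ndarray | None, region_labels: list[str]
) -> np.ndarray:
    resid = residualize(values, covariates)
    sd = resid.std(axis=0)
    dead = np.where(sd <= 0)[0]
    if dead.size:
        names = [region_labels[i] for i in dead]
        raise ValueError(f"zero-variance regions after residualization: {names}")
    mat = np.corrcoef(resid, rowvar=False)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    return mat


def _baseline(frame: pd.DataFrame) -> pd.DataFrame:
    first = frame.groupby("subject_id")["visit_time"].transform("min")
    return frame[frame["visit_time"] == first].drop_duplicates("subject_id")


def _thickness_matrix(frame: pd.DataFrame, thickness_cols: list[str]) -> np.ndarray:
    return frame[thickness_cols].to_numpy(dtype=float)


def thickness_columns(frame: pd.DataFrame) -> list[str]:
    cols = [c for c in frame.columns if c.startswith("thick_")]
    if not cols:
        raise ValueError("no thickness columns (expected 'thick_<region>' names)")
    return cols


def build_reference_network(
    reference: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    baseline_only: bool = True,
) -> ReferenceNetwork:
    """Partial-correlation network across the normative group (baseline rows)."""
    frame = _baseline(reference) if baseline_only else reference
    cols = thickness_columns(frame)
    covs = frame[list(covariates)].to_numpy(dtype=float) if covariates else None
    n = len(frame)
    if n < (0 if covs is None else covs.shape[1]) + 3:
        raise ValueError(f"reference group too small (n={n}) for these covariates")
    regions = [c.removeprefix("thick_") for c in cols]
    mat = _partial_corr_matrix(_thickness_matrix(frame, cols), covs, regions)
    return ReferenceNetwork(mat, n, tuple(covariates), regions)


def _zscore_offdiag(diff: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(diff.shape[0], k=1)
    edges = diff[iu]
    sd = edges.std()
    if sd <= 0:
        raise ValueError("degenerate difference matrix: zero edge variance")
    z_edges = (edges - edges.mean()) / sd
    z = np.zeros_like(diff)
    z[iu] = z_edges
    z = z + z.T
    return z


def build_individual_network(
    subject_visit: pd.Series | pd.DataFrame,
    reference: pd.DataFrame,
    ref_net: ReferenceNetwork,
    covariates: tuple[str, ...] | None = None,
) -> IndividualSimilarityNetwork:
    """Perturbation-based similarity network for one subject-visit.

    The subject's thickness row (with their covariates) is appended to the
    normative baseline data, the partial-correlation network is rebuilt with
    the same covariate adjustment, and the standardized difference from the
    reference network is returned.
    """
    if isinstance(subject_visit, pd.DataFrame):
        if len(subject_visit) != 1:
            raise ValueError("subject_visit must be a single row")
        subject_visit = subject_visit.iloc[0]
    covariates = tuple(covariates) if covariates is not None else ref_net.covariates_used

    base = _baseline(reference)
    cols = [f"thick_{r}" for r in ref_net.region_names]
    for c in cols:
        if c not in subject_visit.index:
            raise ValueError(f"subject row is missing region column {c!r}")
    if subject_visit["subject_id"] in set(base["subject_id"]):
        raise ValueError("subject belongs to the reference group")
    cov_vals = [subject_visit[c] for c in covariates]
    if any(pd.isna(v) for v in cov_vals):
        raise ValueError("subject has missing covariates")

    values = np.vstack(
        [_thickness_matrix(base, cols), np.asarray([subject_visit[c] for c in cols], float)]
    )
    covs = None
    if covariates:
        covs = np.vstack(
            [base[list(covariates)].to_numpy(dtype=float), np.asarray(cov_vals, float)]
        )
    perturbed = _partial_corr_matrix(values, covs, ref_net.region_names)
    diff = perturbed - ref_net.matrix
    diff = (diff + diff.T) / 2.0
    np.fill_diagonal(diff, 0.0)
    z = _zscore_offdiag(diff)
    return IndividualSimilarityNetwork(
        subject_id=str(subject_visit["subject_id"]),
        visit_time=float(subject_visit["visit_time"]),
        z_matrix=z,
        raw_difference=diff,
        region_names=list(ref_net.region_names),
    )


def build_individual_networks(
    targets: pd.DataFrame,
    reference: pd.DataFrame,
    ref_net: ReferenceNetwork,
) -> list[IndividualSimilarityNetwork]:
    """Individual networks for every target subject-visit against one fixed
    baseline reference network."""
    nets = []
    for _, row in targets.iterrows():
        nets.append(build_individual_network(row, reference, ref_net))
    return nets


def similarity_edge_table(
    nets: list[IndividualSimilarityNetwork], regions: list[str]
) -> pd.DataFrame:
    """Long-to-wide table: one row per subject-visit, one column per edge."""
    names = edge_names(regions)
    rows = []
    for net in nets:
        row = {"subject_id": net.subject_id, "visit_time": net.visit_time}
        row.update(dict(zip(names, net.edge_vector("z"))))
        rows.append(row)
    return pd.DataFrame(rows)


def icc_consistency(a: np.ndarray, b: np.ndarray) -> float:
    """Two-way mixed, single-measure, consistency ICC — ICC(3,1).

    Computed from the two-way ANOVA mean squares for n paired measurements by
    k = 2 fixed raters: ``(MSR - MSE) / (MSR + (k - 1) MSE)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom <= 0 or (ss_rows == 0 and ss_err == 0):
        raise ValueError("ICC undefined for zero-variance input")
    return float((msr - mse) / denom)


def stability_curve(
    reference: pd.DataFrame,
    sizes: np.ndarray | list[int],
    n_reps: int = 1000,
    threshold: float = 0.75,
    seed: int = 0,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> StabilityCurve:
    """Mean ICC between subset networks and the full reference network.

    For each sample size, subsets are drawn without replacement ``n_reps``
    times, the partial-correlation network is rebuilt on the subset, and its
    upper-triangle edges are compared to the full network with ICC(3,1).
    ``min_reliable_n`` is the smallest grid size whose mean ICC exceeds the
    reliability threshold (0.75 by default).
    """
    rng = np.random.default_rng(seed)
    base = _baseline(reference)
    full_net = build_reference_network(base, covariates)
    full_edges = full_net.edge_vector()
    n_total = len(base)
    min_size = len(covariates) + 3
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if sizes.max() > n_total:
        raise ValueError(f"max subset size {sizes.max()} exceeds reference n={n_total}")

    kept_sizes, means = [], []
    for size in sizes:
        if size < min_size:
            logger.warning("skipping size %d: too small to residualize", size)
            continue
        iccs = np.empty(n_reps)
        for r in range(n_reps):
            if size == n_total:
                sub = base
            else:
                idx = rng.choice(n_total, size=size, replace=False)
                sub = base.iloc[idx]
            try:
                net = build_reference_network(sub, covariates)
            except ValueError:
                iccs[r] = np.nan
                continue
            iccs[r] = icc_consistency(net.edge_vector(), full_edges)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means.append(float(np.nanmean(iccs)))
        kept_sizes.append(int(size))

    means_arr = np.asarray(means)
    above = [s for s, m in zip(kept_sizes, means_arr) if m > threshold]
    return StabilityCurve(
        sample_sizes=np.asarray(kept_sizes),
        mean_icc=means_arr,
        n_reps=n_reps,
        reliability_threshold=threshold,
        min_reliable_n=(min(above) if above else None),
    )


def save_network_csv(net: ReferenceNetwork | IndividualSimilarityNetwork, path) -> None:
    """Square CSV with region names as header row/column."""
    if isinstance(net, ReferenceNetwork):
        frame = net.to_frame()
    else:
        frame = pd.DataFrame(net.z_matrix, index=net.region_names, columns=net.region_names)
    frame.to_csv(path)


def save_edge_list(matrix: np.ndarray, regions: list[str], path) -> None:
    iu = np.triu_indices(len(regions), k=1)
    frame = pd.DataFrame(
        {
            "region_i": [regions[i] for i in iu[0]],
            "region_j": [regions[j] for j in iu[1]],
            "value": matrix[iu],
        }
    )
    frame.to_csv(path, index=False)
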