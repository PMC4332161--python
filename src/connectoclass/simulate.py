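"""Synthetic two-group cohorts of structural connectivity matrices.

The generator emulates cohorts of nonnegative, symmetric fiber-count matrices
over the 68 bilateral cortical regions, with controllable group effects:

* A single *template*: a degree-heterogeneous (preferential-attachment-like)
  weighted skeleton shared by all subjects, with heavy-tailed (log-normal)
  edge weights — the qualitative signature of real fiber-count matrices.
* Group effects act on the template, before subject noise, so effect sizes
  have one interpretable unit: a *nodal* effect scales the template weight
  mass incident to a chosen region for the patient group; a *global* effect
  rewires a fraction of the patient template's edges, perturbing topology
  (clustering, path structure) while preserving edge count.
* Each subject's matrix is the group template with i.i.d. multiplicative
  log-normal noise per edge.

Default cohort sizes follow the two-group study design the package targets
(18 controls, 14 patients); labels are +1 control, -1 patient.  Clinical
covariates (BDI-II, GAF, age of onset, years since onset) are drawn uniformly
within realistic per-group ranges and left absent (NaN) for controls where
they are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import region_atlas
from .exceptions import ConfigurationError

__all__ = ["CohortConfig", "Cohort", "generate_cohort", "write_cohort", "read_cohort"]

# Per-group uniform covariate ranges (min, max): BDI-II, GAF, age of onset,
# years since onset.  Onset covariates are undefined for controls.
_MDD_COVARIATE_RANGES = {
    "bdi_ii": (22, 43),
    "gaf": (35, 60),
    "age_onset": (3, 26),
    "years_since_onset": (3, 39),
}
_CTL_COVARIATE_RANGES = {"bdi_ii": (0, 11), "gaf": (75, 99)}


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort (a pure function of this
    config plus ``seed``).

    Parameters
    ----------
    n_control, n_mdd : group sizes (>= 2 each).
    n_nodes : network size; 68 uses the bilateral cortical atlas labels.
    base_density : fraction of possible edges present in the template.
    weight_scale : median fiber count per present template edge.
    weight_sigma : log-normal sigma of template edge weights.
    subject_noise_sd : sd of the per-edge multiplicative log-normal
        subject noise (log scale).
    nodal_effect : tuple of (region_index, direction, size) entries; the
        patient template's weights incident to the region are multiplied by
        ``1 + direction * size`` (direction +1/-1).
    global_effect : probability that each patient-template edge is rewired
        to a random non-edge (0 disables).
    covariate_coupling : optional correlation knob linking patient BDI-II to
        the subject's mean log-noise (0 disables).
    """

    n_control: int = 18
    n_mdd: int = 14
    n_nodes: int = 68
    base_density: float = 0.6
    weight_scale: float = 30.0
    weight_sigma: float = 1.0
    subject_noise_sd: float = 0.3
    nodal_effect: tuple = ()
    global_effect: float = 0.0
    covariate_coupling: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_control, (int, np.integer)) or self.n_control < 2:
            raise ConfigurationError(f"n_control must be an integer >= 2, got {self.n_control}")
        if not isinstance(self.n_mdd, (int, np.integer)) or self.n_mdd < 2:
            raise ConfigurationError(f"n_mdd must be an integer >= 2, got {self.n_mdd}")
        if self.n_nodes < 4:
            raise ConfigurationError(f"n_nodes must be >= 4, got {self.n_nodes}")
        if not 0 < self.base_density <= 1:
            raise ConfigurationError(f"base_density must lie in (0, 1], got {self.base_density}")
        if self.weight_scale <= 0:
            raise ConfigurationError(f"weight_scale must be positive, got {self.weight_scale}")
        if self.weight_sigma < 0:
            raise ConfigurationError(f"weight_sigma must be nonnegative, got {self.weight_sigma}")
        if self.subject_noise_sd < 0:
            raise ConfigurationError(
                f"subject_noise_sd must be nonnegative, got {self.subject_noise_sd}"
            )
        if not 0 <= self.global_effect < 1:
            raise ConfigurationError(f"global_effect must lie in [0, 1), got {self.global_effect}")
        for entry in self.nodal_effect:
            if len(entry) != 3:
                raise ConfigurationError(
                    f"nodal_effect entries must be (region, direction, size), got {entry!r}"
                )
            region, direction, size = entry
            if not 0 <= int(region) < self.n_nodes:
                raise ConfigurationError(f"nodal_effect region {region} out of range")
            if direction not in (-1, 1):
                raise ConfigurationError(f"nodal_effect direction must be +1/-1, got {direction}")
            if not np.isfinite(size) or size < 0 or (direction == -1 and size >= 1):
                raise ConfigurationError(f"nodal_effect size invalid: {size}")


@dataclass
class Cohort:
    """A generated (or loaded) cohort: matrices, labels and covariates."""

    subject_ids: list[str]
    matrices: np.ndarray  # (n_subjects, p, p)
    y: np.ndarray  # +1 control, -1 patient
    covariates: pd.DataFrame  # indexed by subject id
    region_labels: list[str]
    config: CohortConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _node_labels(n_nodes: int) -> list[str]:
    if n_nodes == 68:
        return region_atlas()
    return [f"node_{i:03d}" for i in range(n_nodes)]


def _template_skeleton(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Degree-heterogeneous simple graph at exactly floor(density * C(n,2))
    edges: preferential-attachment growth, topped up preferentially."""
    target = int(np.floor(density * n * (n - 1) / 2))
    m = max(1, int(target // n))
    adj = np.zeros((n, n), dtype=bool)
    m0 = min(m + 1, n)
    adj[:m0, :m0] = True  # seed clique
    np.fill_diagonal(adj, False)
    for v in range(m0, n):
        deg = adj.sum(axis=1).astype(float)
        deg[v:] = 0.0
        probs = deg / deg.sum()
        targets = rng.choice(n, size=min(m, v), replace=False, p=probs)
        adj[v, targets] = adj[targets, v] = True
    # top up to the exact edge count, preferring high-degree endpoints
    while int(np.triu(adj, 1).sum()) < target:
        deg = adj.sum(axis=1).astype(float) + 1.0
        ii, jj = np.nonzero(~adj & ~np.eye(n, dtype=bool))
        keep = ii < jj
        ii, jj = ii[keep], jj[keep]
        p = deg[ii] * deg[jj]
        pick = rng.choice(ii.size, p=p / p.sum())
        adj[ii[pick], jj[pick]] = adj[jj[pick], ii[pick]] = True
    return adj


def _rewire(adj: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Move each edge, with probability ``prob``, to a random absent pair."""
    out = adj.copy()
    n = out.shape[0]
    ii, jj = np.nonzero(np.triu(out, 1))
    for a, b in zip(ii, jj):
        if rng.random() >= prob:
            continue
        free_i, free_j = np.nonzero(np.triu(~out, 1) & ~np.eye(n, dtype=bool))
        if free_i.size == 0:
            break
        pick = rng.integers(free_i.size)
        out[a, b] = out[b, a] = False
        out[free_i[pick], free_j[pick]] = out[free_j[pick], free_i[pick]] = True
    return out


def _symmetric_lognormal(n, mu, sigma, rng) -> np.ndarray:
    """Symmetric matrix of i.i.d. log-normal factors on the off-diagonal."""
    vals = rng.lognormal(mean=mu, sigma=sigma, size=(n, n))
    upper = np.triu(vals, 1)
    return upper + upper.T


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a deterministic synthetic cohort from ``config``.

    Controls come first (ids ``CTL01..``, label +1), then patients
    (``MDD01..``, label -1).  Matrices are symmetric, nonnegative with zero
    diagonal; identical configs produce bit-identical cohorts.
    """
    config.validate()
    n = config.n_nodes
    ss = np.random.SeedSequence(config.seed)
    rng_template, rng_group, rng_noise, rng_cov = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    skeleton = _template_skeleton(n, config.base_density, rng_template)
    weights = _symmetric_lognormal(
        n, np.log(config.weight_scale), config.weight_sigma, rng_template
    )
    ctl_template = skeleton * weights

    # patient template: same weights on a possibly rewired skeleton,
    # then nodal weight-mass shifts
    if config.global_effect > 0:
        mdd_skeleton = _rewire(skeleton, config.global_effect, rng_group)
        mdd_template = mdd_skeleton * np.where(
            ctl_template > 0, weights, _symmetric_lognormal(
                n, np.log(config.weight_scale), config.weight_sigma, rng_group
            )
        )
    else:
        mdd_template = ctl_template.copy()
    for region, direction, size in config.nodal_effect:
        factor = 1.0 + direction * size
        region = int(region)
        mdd_template[region, :] *= factor
        mdd_template[:, region] *= factor
        # incident edges scaled once, not twice
        # (row and column both touched only at the diagonal, which is zero)

    n_total = config.n_control + config.n_mdd
    subject_ids = [f"CTL{i + 1:02d}" for i in range(config.n_control)] + [
        f"MDD{i + 1:02d}" for i in range(config.n_mdd)
    ]
    y = np.concatenate(
        [np.ones(config.n_control, dtype=int), -np.ones(config.n_mdd, dtype=int)]
    )

    matrices = np.empty((n_total, n, n))
    log_noise_means = np.empty(n_total)
    for s in range(n_total):
        template = ctl_template if y[s] == 1 else mdd_template
        log_noise = rng_noise.normal(0.0, config.subject_noise_sd, size=(n, n))
        log_noise = np.triu(log_noise, 1)
        log_noise = log_noise + log_noise.T
        matrices[s] = template * np.exp(log_noise)
        present = template > 0
        log_noise_means[s] = log_noise[present].mean() if present.any() else 0.0

    covariates = _draw_covariates(config, y, log_noise_means, rng_cov)
    covariates.index = pd.Index(subject_ids, name="subject_id")
    return Cohort(
        subject_ids=subject_ids,
        matrices=matrices,
        y=y,
        covariates=covariates,
        region_labels=_node_labels(n),
        config=config,
    )


def _draw_covariates(config, y, log_noise_means, rng) -> pd.DataFrame:
    rows = []
    for s, label in enumerate(y):
        if label == -1:
            row = {
                k: float(rng.uniform(lo, hi)) for k, (lo, hi) in _MDD_COVARIATE_RANGES.items()
            }
            if config.covariate_coupling != 0:
                # shift BDI-II toward the subject's noise offset, clipped in range
                lo, hi = _MDD_COVARIATE_RANGES["bdi_ii"]
                shift = config.covariate_coupling * log_noise_means[s] * (hi - lo)
                row["bdi_ii"] = float(np.clip(row["bdi_ii"] + shift, lo, hi))
        else:
            row = {
                k: float(rng.uniform(lo, hi)) for k, (lo, hi) in _CTL_COVARIATE_RANGES.items()
            }
            row["age_onset"] = np.nan
            row["years_since_onset"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_MDD_COVARIATE_RANGES))


# ---------------------------------------------------------------------------
# Serialization: one tab-delimited matrix per subject + a manifest CSV
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, directory) -> Path:
    """Write one labeled TSV matrix per subject plus ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, matrix in zip(cohort.subject_ids, cohort.matrices):
        frame = pd.DataFrame(matrix, index=cohort.region_labels, columns=cohort.region_labels)
        frame.to_csv(directory / f"{sid}.tsv", sep="\t")
    manifest = cohort.covariates.copy()
    manifest.insert(0, "group", cohort.y)
    manifest.to_csv(directory / "manifest.csv")
    return directory


def read_cohort(directory) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (or hand-prepared in the
    same layout).  Raises FileNotFoundError naming any missing subject file."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", index_col="subject_id")
    subject_ids = [str(s) for s in manifest.index]
    matrices = []
    region_labels: list[str] | None = None
    for sid in subject_ids:
        path = directory / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"matrix file missing for subject {sid!r}: {path}")
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if region_labels is None:
            region_labels = [str(c) for c in frame.columns]
        matrices.append(frame.to_numpy(dtype=float))
    y = manifest.pop("group").to_numpy(dtype=int)
    return Cohort(
        subject_ids=subject_ids,
        matrices=np.stack(matrices),
        y=y,
        covariates=manifest,
        region_labels=region_labels or [],
        config=None,
    )
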