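"""Containers and CSV I/O for repeated point-count survey data.

The survey design is a set of sites, each visited on a variable number of
occasions (replicates); on each occasion every species seen is counted.
Because the number of replicates varies by site, the count tensor is stored
dense with an explicit boolean mask marking which (site, replicate) cells
correspond to surveys that actually happened.  Zeros inside the mask are
real observations ("no birds seen"); cells outside the mask carry no
information and are ignored by every likelihood in the package.

Site covariates are distances, in kilometres, from each point-count site to
the nearest instance of five classes of human construction: primary roads,
secondary roads, fences, human settlements, and cities.  Before modelling,
all five are standardized to mean 0 and sample standard deviation 1
(divisor n - 1), so coefficients on different covariates are directly
comparable and a *negative* coefficient means the response *increases*
with proximity to that feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical order of the five anthropogenic feature classes.
FEATURE_CLASSES = ("primary_road", "secondary_road", "fence", "settlement", "city")

#: Column names used in covariate CSV files, same order as FEATURE_CLASSES.
DISTANCE_COLUMNS = (
    "d_primary_km",
    "d_secondary_km",
    "d_fence_km",
    "d_settlement_km",
    "d_city_km",
)


class SchemaError(ValueError):
    """A CSV file is missing required columns."""


class ValidationError(ValueError):
    """Input records violate the data contract (negative counts, duplicates, ...)."""


class DegenerateCovariateError(ValueError):
    """A covariate column is constant and cannot be standardized."""


@dataclass
class SurveyCounts:
    """Ragged site x replicate x species counts from repeated point counts.

    Attributes
    ----------
    counts : (S, Jmax, K) int array
        Number of individuals of species k counted at site i on replicate j.
    replicate_mask : (S, Jmax) bool array
        True where a survey actually took place.  Counts outside the mask
        are kept at zero and are never used.
    site_ids, species_names : lists of labels, lengths S and K.
    """

    counts: np.ndarray
    replicate_mask: np.ndarray
    site_ids: list[str]
    species_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.replicate_mask = np.asarray(self.replicate_mask, dtype=bool)
        if self.counts.ndim != 3:
            raise ValidationError("counts must be a (site, replicate, species) tensor")
        s, j, k = self.counts.shape
        if self.replicate_mask.shape != (s, j):
            raise ValidationError("replicate_mask shape must match counts[:, :, 0]")
        if len(self.site_ids) != s or len(self.species_names) != k:
            raise ValidationError("label lengths must match tensor dimensions")
        if len(set(self.species_names)) != k:
            raise ValidationError("species names must be unique")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        if np.any(self.replicate_mask.sum(axis=1) < 1):
            raise ValidationError("every site needs at least one surveyed replicate")
        # zero out anything outside the mask so masked cells can never leak
        self.counts = np.where(self.replicate_mask[:, :, None], self.counts, 0)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[2]

    @property
    def surveys_per_site(self) -> np.ndarray:
        """Number of replicates actually surveyed at each site, J_i."""
        return self.replicate_mask.sum(axis=1)

    def species_totals(self) -> np.ndarray:
        """Total count per species over all surveyed cells."""
        return self.counts.sum(axis=(0, 1))

    def select_species(self, name: str) -> "SurveyCounts":
        """Single-species view, keeping the full replicate structure."""
        k = self.species_names.index(name)
        return SurveyCounts(
            counts=self.counts[:, :, k : k + 1].copy(),
            replicate_mask=self.replicate_mask.copy(),
            site_ids=list(self.site_ids),
            species_names=[name],
        )

    def total_abundance(self) -> "SurveyCounts":
        """Counts summed over species per (site, replicate): the input for a
        total-abundance model."""
        tot = self.counts.sum(axis=2, keepdims=True)
        return SurveyCounts(
            counts=tot,
            replicate_mask=self.replicate_mask.copy(),
            site_ids=list(self.site_ids),
            species_names=["all_species"],
        )


@dataclass
class DetectionHistory:
    """Binary detection / non-detection histories per site, replicate, species."""

    detections: np.ndarray
    replicate_mask: np.ndarray
    site_ids: list[str]
    species_names: list[str]

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections)
        self.replicate_mask = np.asarray(self.replicate_mask, dtype=bool)
        if not np.all(np.isin(self.detections, (0, 1))):
            raise ValidationError("detections must be 0/1")
        self.detections = self.detections.astype(np.int8)
        self.detections = np.where(self.replicate_mask[:, :, None], self.detections, 0)

    @property
    def n_sites(self) -> int:
        return self.detections.shape[0]

    @property
    def n_species(self) -> int:
        return self.detections.shape[2]

    @property
    def surveys_per_site(self) -> np.ndarray:
        return self.replicate_mask.sum(axis=1)

    def detections_per_site(self) -> np.ndarray:
        """(S, K) number of replicates on which each species was detected."""
        return self.detections.sum(axis=1)


def binarize(counts: SurveyCounts) -> DetectionHistory:
    """Collapse counts to detection (count > 0) / non-detection histories."""
    return DetectionHistory(
        detections=(counts.counts > 0).astype(np.int8),
        replicate_mask=counts.replicate_mask.copy(),
        site_ids=list(counts.site_ids),
        species_names=list(counts.species_names),
    )


@dataclass
class SiteCovariates:
    """Per-site distances (km) to the five anthropogenic feature classes.

    ``raw`` holds distances in km; ``standardized`` (filled by
    :func:`standardize_covariates`) holds the mean-0 / sd-1 versions used by
    the linear predictors, with the centering constants retained so either
    scale can be recovered from the other.
    """

    site_ids: list[str]
    raw: np.ndarray  # (S, C) distances in km
    feature_names: tuple[str, ...] = FEATURE_CLASSES
    standardized: np.ndarray | None = None
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[0] != len(self.site_ids):
            raise ValidationError("raw must be (n_sites, n_features)")
        if self.raw.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length must match raw columns")
        if np.any(self.raw < 0):
            raise ValidationError("distances must be nonnegative")

    @property
    def n_sites(self) -> int:
        return self.raw.shape[0]

    @property
    def x(self) -> np.ndarray:
        """Standardized design matrix; raises if not yet standardized."""
        if self.standardized is None:
            raise ValidationError(
                "covariates are not standardized; call standardize_covariates first"
            )
        return self.standardized

    def unstandardize(self) -> np.ndarray:
        """Invert the standardization: standardized * sd + mean."""
        if self.standardized is None or self.sds is None:
            raise ValidationError("no standardization constants stored")
        return self.standardized * self.sds + self.means


def standardize_covariates(cov: SiteCovariates) -> SiteCovariates:
    """Return a copy with each distance column centred to mean 0 and scaled
    to sample standard deviation 1 (divisor n - 1).

    Raises
    ------
    DegenerateCovariateError
        If any column is constant (zero variance), naming the column.
    """
    if cov.n_sites < 2:
        raise ValidationError("standardization needs at least 2 sites")
    means = cov.raw.mean(axis=0)
    sds = cov.raw.std(axis=0, ddof=1)
    for name, sd in zip(cov.feature_names, sds):
        if sd == 0.0:
            raise DegenerateCovariateError(f"covariate column '{name}' is constant")
    return replace(
        cov,
        raw=cov.raw.copy(),
        standardized=(cov.raw - means) / sds,
        means=means,
        sds=sds,
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Counts travel in long format (site, replicate, species, count):
# the ragged replicate structure makes wide format awkward.  A replicate is
# considered surveyed iff at least one row for that (site, replicate) pair
# appears in the file; species without a row at a surveyed replicate are
# zero-filled.
# ---------------------------------------------------------------------------

_COUNT_SCHEMA = {"site": "site", "replicate": "replicate", "species": "species", "count": "count"}


def read_counts_csv(path, schema: dict[str, str] | None = None) -> SurveyCounts:
    """Read long-format count data into a :class:`SurveyCounts` tensor.

    Parameters
    ----------
    path : file path
    schema : optional map from the logical column names
        (site, replicate, species, count) to the names used in the file.
    """
    colmap = dict(_COUNT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    counts_col = pd.to_numeric(df["count"], errors="coerce")
    if counts_col.isna().any():
        raise ValidationError("non-numeric count value")
    if np.any(counts_col != np.floor(counts_col)):
        raise ValidationError("counts must be integers")
    if np.any(counts_col < 0):
        raise ValidationError("negative count")
    df["count"] = counts_col.astype(np.int64)

    if df.duplicated(subset=["site", "replicate", "species"]).any():
        raise ValidationError("duplicate (site, replicate, species) row")

    site_ids = sorted(df["site"].astype(str).unique())
    species = sorted(df["species"].astype(str).unique())
    reps = pd.to_numeric(df["replicate"], errors="coerce")
    if reps.isna().any() or np.any(reps != np.floor(reps)) or np.any(reps < 1):
        raise ValidationError("replicate must be a positive integer index")
    df["replicate"] = reps.astype(int)

    jmax = int(df["replicate"].max())
    s_index = {s: i for i, s in enumerate(site_ids)}
    k_index = {k: i for i, k in enumerate(species)}

    counts = np.zeros((len(site_ids), jmax, len(species)), dtype=np.int64)
    mask = np.zeros((len(site_ids), jmax), dtype=bool)
    si = df["site"].astype(str).map(s_index).to_numpy()
    ji = df["replicate"].to_numpy() - 1
    ki = df["species"].astype(str).map(k_index).to_numpy()
    counts[si, ji, ki] = df["count"].to_numpy()
    mask[si, ji] = True
    return SurveyCounts(counts=counts, replicate_mask=mask, site_ids=site_ids, species_names=species)


def write_counts_csv(sc: SurveyCounts, path) -> None:
    """Write counts in the same long format ``read_counts_csv`` accepts.

    Every surveyed (site, replicate) pair is written for every species,
    zeros included, so the replicate mask round-trips exactly.
    """
    rows = []
    for i, site in enumerate(sc.site_ids):
        for j in range(sc.counts.shape[1]):
            if not sc.replicate_mask[i, j]:
                continue
            for k, sp in enumerate(sc.species_names):
                rows.append((site, j + 1, sp, int(sc.counts[i, j, k])))
    pd.DataFrame(rows, columns=["site", "replicate", "species", "count"]).to_csv(
        path, index=False
    )


def read_covariates_csv(path) -> SiteCovariates:
    """Read the companion per-site covariate table (distances in km)."""
    df = pd.read_csv(path)
    missing = [c for c in ("site",) + DISTANCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.sort_values("site", key=lambda s: s.astype(str)).reset_index(drop=True)
    return SiteCovariates(
        site_ids=df["site"].astype(str).tolist(),
        raw=df[list(DISTANCE_COLUMNS)].to_numpy(dtype=float),
    )


def write_covariates_csv(cov: SiteCovariates, path) -> None:
    df = pd.DataFrame(cov.raw, columns=list(DISTANCE_COLUMNS))
    df.insert(0, "site", cov.site_ids)
    df.to_csv(path, index=False)
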