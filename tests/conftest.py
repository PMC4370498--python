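import numpy as np
import pytest

from raptorcount import (
    DesignConfig,
    SiteCovariates,
    generate_design,
    standardize_covariates,
)
from raptorcount.simulate import StudyDesign


@pytest.fixture(scope="session")
def design77():
    """One realized 77-site study landscape, standardized covariates."""
    return generate_design(DesignConfig(n_sites_target=77), seed=11)


@pytest.fixture(scope="session")
def design88():
    return generate_design(DesignConfig(), seed=11)


def make_design(X_raw, n_replicates, site_prefix="s"):
    """Construct a StudyDesign directly from a raw covariate matrix, for
    small hand-built test problems."""
    X_raw = np.asarray(X_raw, dtype=float)
    names = tuple(f"x{c+1}" for c in range(X_raw.shape[1]))
    cov = standardize_covariates(
        SiteCovariates(
            site_ids=[f"{site_prefix}{i+1}" for i in range(X_raw.shape[0])],
            raw=X_raw,
            feature_names=names,
        )
    )
    return StudyDesign(
        covariates=cov,
        n_replicates=np.asarray(n_replicates, dtype=int),
        site_xy=np.zeros((X_raw.shape[0], 2)),
    )
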