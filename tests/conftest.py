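"""Shared fixtures: synthetic reference panels at the scales the tests use."""

import numpy as np
import pandas as pd
import pytest

import methyldeconv as md


@pytest.fixture(scope="session")
def small5_design():
    """Five cell types, 100 planted probes: fast deconvolution fixture."""
    return md.SyntheticDesign(
        cell_types=("A", "B", "C", "D", "E"),
        n_probes=300,
        n_informative_per_pair=10,
        seed=5,
    )


@pytest.fixture(scope="session")
def small5_synth(small5_design):
    return md.generate_reference(small5_design)


@pytest.fixture(scope="session")
def small5_sig(small5_synth):
    sig, _, _ = md.derive_signature(small5_synth.reference)
    return sig


@pytest.fixture(scope="session")
def mid_design():
    """Nine cell types, 432 planted probes: full-panel fixture."""
    return md.SyntheticDesign(n_probes=600, n_informative_per_pair=12, seed=101)


@pytest.fixture(scope="session")
def mid_synth(mid_design):
    return md.generate_reference(mid_design)


@pytest.fixture(scope="session")
def mid_sig(mid_synth):
    sig, _, _ = md.derive_signature(mid_synth.reference)
    return sig


@pytest.fixture
def tiny_beta():
    """Hand-written 3-probe x 2-sample beta matrix."""
    return md.BetaMatrix(
        pd.DataFrame(
            {"s1": [0.1, 0.5, 0.9], "s2": [0.2, 0.6, 1.0]},
            index=["cg1", "cg2", "cg3"],
        )
    )


def nnls_fractions(sig, mixture_betas):
    """Independent non-negative-least-squares oracle on the standardised system.

    Same standardisation as the deconvolution engine; the intercept is free
    (split into +/- non-negative parts) to mirror the SVR bias term.
    """
    from scipy.optimize import nnls

    X_raw = sig.data.to_numpy(dtype=float)
    X = (X_raw - X_raw.mean()) / X_raw.std()
    y_raw = mixture_betas.loc[sig.probe_ids].to_numpy(dtype=float) * 100.0
    y = (y_raw - y_raw.mean()) / y_raw.std()
    n = X.shape[0]
    A = np.hstack([X, np.ones((n, 1)), -np.ones((n, 1))])
    w, _ = nnls(A, y)
    w = w[: X.shape[1]]
    return pd.Series(w / w.sum(), index=sig.cell_types)
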