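"""TMB, signature refitting, BRCAness / MMRd / MSI flags."""

import numpy as np
import pandas as pd
import pytest

from mtbmatch.biomarkers import (
    CONTEXTS_96,
    MutationCatalog,
    SignatureExposures,
    brcaness_score,
    compute_tmb,
    default_reference_signatures,
    load_reference_signatures,
    mmrd_flag,
    msi_status,
    refit_signatures,
    synthetic_reference_signatures,
)
from mtbmatch.variants import Effect
from tests.test_variants import make_variant


@pytest.fixture(scope="module")
def reference():
    return default_reference_signatures()


# ---------------------------------------------------------------------------
# TMB

def test_tmb_arithmetic_and_synonymous_exclusion():
    variants = [make_variant(pos=i + 1) for i in range(122)]
    assert compute_tmb(variants, 30.0) == pytest.approx(122 / 30)
    with_syn = variants + [make_variant(pos=999, effect=Effect.SYNONYMOUS)]
    assert compute_tmb(with_syn, 30.0) == pytest.approx(122 / 30)


def test_tmb_scales_linearly():
    variants = [make_variant(pos=i + 1) for i in range(50)]
    assert compute_tmb(variants * 2, 30.0) == \
        pytest.approx(2 * compute_tmb(variants, 30.0))
    assert compute_tmb([], 30.0) == 0.0


def test_tmb_high_boundary_inclusive():
    variants = [make_variant(pos=i + 1) for i in range(300)]
    assert compute_tmb(variants, 30.0) == pytest.approx(10.0)
    # >= 10 mut/Mb is TMB-high
    assert compute_tmb(variants, 30.0) >= 10.0


def test_tmb_rejects_bad_denominator():
    with pytest.raises(ValueError):
        compute_tmb([], 0.0)


# ---------------------------------------------------------------------------
# signature refitting

def test_reference_columns_are_probability_vectors(reference):
    np.testing.assert_allclose(reference.sum(axis=0), 1.0, atol=1e-6)
    assert list(reference.index) == CONTEXTS_96


def test_bundled_matrix_matches_generator(reference):
    regenerated = synthetic_reference_signatures()
    np.testing.assert_allclose(reference.to_numpy(),
                               regenerated.to_numpy(), atol=1e-5)


def test_refit_self_recovery_single_signature(reference):
    catalog = MutationCatalog(
        np.round(1000 * reference["SBS6"].to_numpy()))
    exposures = refit_signatures(catalog, reference)
    assert exposures.fraction("SBS6") >= 0.99
    assert exposures.residual < 0.05


def test_refit_zero_catalog_flags_empty(reference):
    exposures = refit_signatures(MutationCatalog(np.zeros(96)), reference)
    assert exposures.empty
    assert all(v == 0.0 for v in exposures.exposures.values())


def test_refit_recovers_mixture_within_tolerance(reference):
    rng = np.random.default_rng(20230227)
    truth = {"SBS6": 0.6, "SBS26": 0.4}
    probs = sum(frac * reference[name].to_numpy()
                for name, frac in truth.items())
    catalog = MutationCatalog(rng.multinomial(10_000, probs).astype(float))
    exposures = refit_signatures(catalog, reference)
    for name, frac in truth.items():
        assert exposures.fraction(name) == pytest.approx(frac, abs=0.03)


def test_refit_exact_mixture_is_grid_optimal(reference):
    """NNLS optimum checked against a coarse brute-force grid search."""
    truth = np.array([0.0, 0.3, 0.7, 0.0, 0.0])
    counts = 5000 * (reference.to_numpy() @ truth)
    catalog = MutationCatalog(counts)
    exposures = refit_signatures(catalog, reference)
    fit = np.array([exposures.exposures[c] for c in reference.columns])
    matrix = reference.to_numpy()

    def loss(weights):
        return np.linalg.norm(matrix @ (5000 * weights) - counts)

    best_grid = min(
        ((a / 10, b / 10, 1 - a / 10 - b / 10)
         for a in range(11) for b in range(11 - a)),
        key=lambda w: loss(np.array([0.0, w[0], w[1], 0.0, w[2]])))
    assert loss(fit) <= loss(
        np.array([0.0, best_grid[0], best_grid[1], 0.0, best_grid[2]])) + 1e-6
    np.testing.assert_allclose(fit, truth, atol=1e-6)
    assert exposures.residual == pytest.approx(0.0, abs=1e-9)


def test_refit_invariant_to_column_permutation(reference):
    catalog = MutationCatalog(
        np.round(2000 * (0.5 * reference["SBS6"].to_numpy()
                         + 0.5 * reference["SBS1"].to_numpy())))
    baseline = refit_signatures(catalog, reference)
    permuted = refit_signatures(catalog, reference[list(reference.columns)[::-1]])
    for name in reference.columns:
        assert permuted.fraction(name) == \
            pytest.approx(baseline.fraction(name), abs=1e-9)


def test_load_reference_rejects_incomplete_matrix(tmp_path):
    df = synthetic_reference_signatures().iloc[:90]
    path = tmp_path / "ref.tsv"
    df.to_csv(path, sep="\t")
    with pytest.raises(ValueError, match="contexts"):
        load_reference_signatures(path)


# ---------------------------------------------------------------------------
# flags

@pytest.mark.parametrize("fraction,positive", [
    (0.25, True), (0.20, True), (0.199, False), (0.0, False),
])
def test_brcaness_cutoff_inclusive(fraction, positive):
    exposures = SignatureExposures({"SBS6": fraction, "SBS5": 1 - fraction})
    got_fraction, got_positive = brcaness_score(exposures)
    assert got_fraction == fraction
    assert got_positive is positive


def test_brcaness_requires_sbs6_in_reference():
    with pytest.raises(KeyError, match="SBS6"):
        brcaness_score(SignatureExposures({"SBS1": 1.0}))


@pytest.mark.parametrize("exposures,expected", [
    ({"SBS26": 0.5, "SBS5": 0.3, "SBS1": 0.2}, True),
    ({"SBS26": 0.3, "SBS5": 0.3, "SBS1": 0.4}, False),
    ({"SBS26": 0.3, "SBS5": 0.3}, False),          # tie: not predominant
    ({"SBS1": 1.0}, False),
])
def test_mmrd_predominance_strict_maximum(exposures, expected):
    assert mmrd_flag(SignatureExposures(exposures)) is expected


def test_msi_status_threshold_and_missing():
    assert msi_status(25.0, 10.0) == (True, False)
    assert msi_status(10.0, 10.0) == (True, False)
    assert msi_status(9.9, 10.0) == (False, False)
    assert msi_status(None, 10.0) == (False, True)   # untested, not high
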