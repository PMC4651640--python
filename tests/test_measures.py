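"""Intragene measure definitions, filtering, and the concordance check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intrameth.io import Dataset
from intrameth.measures import (
    GeneProfile,
    MEASURES,
    asymm_measure,
    build_profiles,
    compute_measure_matrix,
    deriv_measure,
    dev_measure,
    kendall_concordance,
    kendall_critical_value,
    kendall_w,
    mean_measure,
    var_measure,
)
from tests.conftest import random_profile


def profile(betas, coords=None):
    betas = np.asarray(betas, dtype=float)
    if coords is None:
        coords = np.arange(1, len(betas) + 1) * 100
    return GeneProfile("G", betas, np.asarray(coords))


# ---------------------------------------------------------------------------
# hand-checked values


@pytest.mark.parametrize(
    "func, betas, coords, expected",
    [
        (mean_measure, [0.2, 0.4, 0.6, 0.8, 1.0], None, 0.6),
        (mean_measure, [0.5] * 5, None, 0.5),
        (var_measure, [0.5] * 5, None, 0.0),
        (var_measure, [0, 0, 0, 1, 1], None, 0.3),
        (deriv_measure, [0.5] * 5, None, 0.0),
        (deriv_measure, [0, 0.25, 0.5, 0.75, 1.0], None, 0.25),
        (deriv_measure, [0.1, 0.5, 0.3, 0.3, 0.3], None, 0.15),
        # chord from (0, 0.1) to (400, 0.3) passes 0.1,0.15,0.2,0.25,0.3
        (dev_measure, [0.1, 0.5, 0.3, 0.25, 0.3], [0, 100, 200, 300, 400], 0.45),
        (dev_measure, [0.2, 0.4, 0.6, 0.8, 1.0], None, 0.0),  # collinear
        (asymm_measure, [1.0, 0.8, 0.6, 0.4, 0.2], None, 1.0),
        (asymm_measure, [0.2, 0.4, 0.6, 0.8, 1.0], None, 0.0),
        (asymm_measure, [0.1, 0.5, 0.3, 0.3, 0.4], None, 2.0 / 7.0),
        (asymm_measure, [0.5] * 5, None, 0.5),  # no variation -> neutral
    ],
)
def test_measure_hand_examples(func, betas, coords, expected):
    assert func(profile(betas, coords)) == pytest.approx(expected, abs=1e-12)


def test_dev_endpoint_terms_are_zero():
    """The chord interpolates the endpoints, so they never contribute."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = random_profile(rng)
        b, c = p.betas, p.coords
        span = c[-1] - c[0]
        chord = b[0] + (b[-1] - b[0]) / span * (c - c[0])
        inner = float(np.sum(np.abs(chord - b)[1:-1]))
        assert dev_measure(p) == pytest.approx(inner, abs=1e-12)


def _loop_oracle(p: GeneProfile) -> dict[str, float]:
    """Naive per-definition computation, independent of the library path."""
    b, c, n = list(p.betas), list(p.coords), p.n
    mean = sum(b) / n
    var = sum((x - mean) ** 2 for x in b) / (n - 1)
    deriv = sum(abs(b[i] - b[i + 1]) for i in range(n - 1)) / (n - 1)
    span = c[-1] - c[0]
    dev = sum(
        abs(b[0] + (b[-1] - b[0]) / span * (c[i] - c[0]) - b[i]) for i in range(n)
    )
    dec = sum(b[i] - b[i + 1] for i in range(n - 1) if b[i] > b[i + 1])
    tot = sum(abs(b[i] - b[i + 1]) for i in range(n - 1))
    asymm = dec / tot if tot > 0 else 0.5
    return {"MEAN": mean, "VAR": var, "DERIV": deriv, "DEV": dev, "ASYMM": asymm}


def test_measures_match_loop_oracle_on_random_profiles():
    rng = np.random.default_rng(1)
    funcs = {
        "MEAN": mean_measure,
        "VAR": var_measure,
        "DERIV": deriv_measure,
        "DEV": dev_measure,
        "ASYMM": asymm_measure,
    }
    for _ in range(100):
        p = random_profile(rng)
        expected = _loop_oracle(p)
        for name, func in funcs.items():
            assert func(p) == pytest.approx(expected[name], abs=1e-10), name


# ---------------------------------------------------------------------------
# algebraic properties


def test_translation_invariance():
    """Adding a constant shifts MEAN by it and leaves the rest unchanged."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        p = random_profile(rng)
        c = float(rng.uniform(0, 1 - p.betas.max()))
        q = GeneProfile(p.gene, p.betas + c, p.coords)
        assert mean_measure(q) == pytest.approx(mean_measure(p) + c, abs=1e-10)
        for func in (var_measure, deriv_measure, dev_measure, asymm_measure):
            assert func(q) == pytest.approx(func(p), abs=1e-10)


def test_reversal_property():
    """Reversing the profile flips ASYMM to 1-ASYMM, fixes the rest."""
    rng = np.random.default_rng(3)
    for _ in range(200):
        p = random_profile(rng)
        if np.any(np.diff(p.betas) == 0):  # ties make the flip inexact
            continue
        rev = GeneProfile(p.gene, p.betas[::-1], np.sort(p.coords[-1] - p.coords))
        assert asymm_measure(rev) == pytest.approx(1 - asymm_measure(p), abs=1e-10)
        for func in (mean_measure, var_measure, deriv_measure, dev_measure):
            assert func(rev) == pytest.approx(func(p), abs=1e-10)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    betas=st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=30),
    gap=st.integers(1, 1000),
)
def test_measure_ranges(betas, gap):
    """MEAN, DERIV, ASYMM stay in [0,1]; VAR and DEV are non-negative."""
    p = profile(betas, coords=np.arange(1, len(betas) + 1) * gap)
    assert 0.0 <= mean_measure(p) <= 1.0
    assert var_measure(p) >= 0.0
    assert 0.0 <= deriv_measure(p) <= 1.0
    assert 0.0 <= asymm_measure(p) <= 1.0
    assert dev_measure(p) >= 0.0


# ---------------------------------------------------------------------------
# profile construction and the gene filter


def _toy_dataset(manifest_rows, n_samples=2, seed=0):
    manifest = pd.DataFrame(
        manifest_rows, columns=["probe_id", "chromosome", "coordinate", "gene"]
    )
    rng = np.random.default_rng(seed)
    betas = pd.DataFrame(
        rng.uniform(0, 1, size=(len(manifest), n_samples)),
        index=manifest["probe_id"].to_numpy(),
        columns=[f"S{i}" for i in range(n_samples)],
    )
    labels = pd.Series(
        ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2),
        index=betas.columns,
    )
    return Dataset(betas=betas, manifest=manifest, labels=labels)


def test_gene_filter_boundary():
    """Genes need at least five probes: four is out, five is in."""
    rows = [(f"p{i}", "chr1", 100 * (i + 1), "SHORT") for i in range(4)]
    rows += [(f"q{i}", "chr1", 100 * (i + 1), "OK") for i in range(5)]
    ds = _toy_dataset(rows)
    profiles = build_profiles(ds)
    for sample_profiles in profiles.values():
        assert "SHORT" not in sample_profiles
        assert "OK" in sample_profiles


def test_probes_sorted_by_coordinate():
    rows = [(f"p{i}", "chr1", coord, "G") for i, coord in enumerate([500, 100, 300, 200, 400])]
    ds = _toy_dataset(rows)
    prof = build_profiles(ds)["S0"]["G"]
    assert list(prof.coords) == [100, 200, 300, 400, 500]
    by_probe = dict(zip(ds.manifest["coordinate"], ds.manifest["probe_id"]))
    expected = [float(ds.betas.at[by_probe[c], "S0"]) for c in prof.coords]
    assert list(prof.betas) == pytest.approx(expected)


def test_multichromosome_gene_split_and_refilter():
    """A gene on two chromosomes splits; each part refilters at >=5 probes."""
    rows = [(f"a{i}", "chr1", 100 * (i + 1), "G") for i in range(5)]
    rows += [(f"b{i}", "chr2", 100 * (i + 1), "G") for i in range(3)]
    ds = _toy_dataset(rows)
    profiles = build_profiles(ds)["S0"]
    assert set(profiles) == {"G@chr1"}  # chr2 part has <5 probes


def test_coordinate_ties_keep_first():
    rows = [(f"p{i}", "chr1", c, "G") for i, c in enumerate([100, 200, 200, 300, 400, 500])]
    ds = _toy_dataset(rows)
    prof = build_profiles(ds)["S0"]["G"]
    assert list(prof.coords) == [100, 200, 300, 400, 500]
    assert prof.betas[1] == pytest.approx(float(ds.betas.at["p1", "S0"]))


def test_matrix_matches_profile_functions(tiny_dataset):
    """Vectorized table equals the per-profile operations, cell by cell."""
    matrix = compute_measure_matrix(tiny_dataset)
    profiles = build_profiles(tiny_dataset)
    funcs = dict(
        MEAN=mean_measure, VAR=var_measure, DERIV=deriv_measure,
        DEV=dev_measure, ASYMM=asymm_measure,
    )
    rng = np.random.default_rng(4)
    samples = list(matrix.index)
    for sample in rng.choice(samples, size=3, replace=False):
        for gene, prof in profiles[sample].items():
            for m, func in funcs.items():
                assert matrix.at[sample, f"{gene}|{m}"] == pytest.approx(
                    func(prof), abs=1e-10
                )


def test_matrix_shape_and_measure_subset(tiny_dataset):
    full = compute_measure_matrix(tiny_dataset)
    n_genes = full.shape[1] // 5
    assert full.shape == (tiny_dataset.betas.shape[1], 5 * n_genes)
    mean_only = compute_measure_matrix(tiny_dataset, ["MEAN"])
    assert mean_only.shape[1] == n_genes
    assert all(c.endswith("|MEAN") for c in mean_only.columns)
    with pytest.raises(ValueError, match="unknown measure"):
        compute_measure_matrix(tiny_dataset, ["MEAN", "MEDIAN"])


# ---------------------------------------------------------------------------
# Kendall concordance


def test_kendall_perfect_and_reversed():
    m = 10
    base = np.arange(m, dtype=float)
    assert kendall_w(np.vstack([base] * 5)) == pytest.approx(1.0)
    assert kendall_w(np.vstack([base, base[::-1]])) == pytest.approx(0.0, abs=1e-12)


def test_kendall_critical_value_matches_chi2():
    from scipy import stats

    crit = kendall_critical_value(5, 50, alpha=0.05)
    assert crit == pytest.approx(stats.chi2.ppf(0.95, 49) / (5 * 49))


def test_kendall_concordance_frame(tiny_dataset):
    matrix = compute_measure_matrix(tiny_dataset)
    out = kendall_concordance(matrix)
    assert list(out.index) == list(matrix.index)
    assert ((out["W"] >= 0) & (out["W"] <= 1)).all()
    assert out["critical_value"].nunique() == 1  # one common critical value
    # measures computed from the same profiles are correlated, so most
    # samples should clear the independence critical value
    assert out["significant"].mean() > 0.5


def test_kendall_requires_all_measures(tiny_dataset):
    matrix = compute_measure_matrix(tiny_dataset, ["MEAN", "VAR"])
    with pytest.raises(ValueError, match="all five"):
        kendall_concordance(matrix)
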