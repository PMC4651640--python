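"""Synthetic 450K-style methylation data with planted class effects.

The generator emulates the shape of a two-group stem-cell methylation
study: a probe manifest in which every gene carries at least five
coordinate-ordered CpG probes, a beta matrix for two classes of samples
(defaults 31 vs 35), and GMT gene-set collections with controlled
overlap against the genes carrying planted effects.

Class differences are planted as shifts in the expected value of a
single intragene measure for a chosen gene subset, so that pipeline
recovery of the planted genes is checkable against ground truth:

* ``MEAN``  — an additive shift of all probe means,
* ``VAR`` / ``DERIV`` — an alternating (zigzag) offset that inflates
  probe-to-probe dispersion,
* ``ASYMM`` — probe means replaced by a strictly decreasing linear
  ramp, driving the asymmetry toward 1,
* ``DEV``   — a triangular bump peaking mid-gene, off the endpoint
  chord.

Per-probe noise is Gaussian, clipped to [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASURE_NAMES = ("MEAN", "VAR", "DERIV", "DEV", "ASYMM")

#: spread of the per-probe offsets around the gene baseline mean
PROBE_OFFSET_SD = 0.05

DEFAULT_CLASS_NAMES = ("ESC", "iPSC")

_CHROMOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass(frozen=True)
class EffectSpec:
    """A planted two-class difference in one intragene measure.

    ``effect_size`` is on the scale of the targeted measure's shift of
    probe means; ``noise_sd`` overrides the global per-probe noise for
    the target genes.
    """

    target_genes: tuple[str, ...]
    measure: str
    effect_size: float
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_genes", tuple(self.target_genes))
        if self.measure not in MEASURE_NAMES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class LabeledBetaMatrix:
    """Probe x sample beta matrix with per-sample class labels."""

    betas: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.labels) != self.betas.shape[1]:
            raise ValueError("label vector length must equal sample count")
        vals = self.betas.to_numpy()
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("beta values must lie in [0, 1]")


def generate_manifest(
    n_genes: int,
    probes_per_gene: tuple[int, int] = (5, 20),
    coordinate_spacing: tuple[int, int] = (50, 500),
    seed: int = 0,
) -> pd.DataFrame:
    """Probe manifest with contiguous, strictly increasing coordinates.

    Genes are laid out consecutively along chromosomes assigned
    round-robin; each gene gets a probe count drawn uniformly from
    ``probes_per_gene`` (inclusive) and inter-probe spacings drawn from
    ``coordinate_spacing``.  The lower probe bound must be at least 5 so
    every synthetic gene survives the minimum-probe filter.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = probes_per_gene
    if lo < 5:
        raise ValueError("probes_per_gene lower bound must be >= 5")
    if hi < lo:
        raise ValueError("probes_per_gene range inverted")
    s_lo, s_hi = coordinate_spacing
    if s_lo < 1 or s_hi < s_lo:
        raise ValueError("coordinate_spacing must be a positive range")

    rng = np.random.default_rng(seed)
    counts = rng.integers(lo, hi + 1, size=n_genes)
    width = len(str(n_genes))
    gene_names = [f"GENE{i:0{width}d}" for i in range(1, n_genes + 1)]

    rows = []
    chrom_cursor = {c: 10_000 for c in _CHROMOSOMES}
    probe_no = 1
    for g, (gene, count) in enumerate(zip(gene_names, counts)):
        chrom = _CHROMOSOMES[g % len(_CHROMOSOMES)]
        gaps = rng.integers(s_lo, s_hi + 1, size=count)
        coords = chrom_cursor[chrom] + np.cumsum(gaps)
        chrom_cursor[chrom] = int(coords[-1]) + 5_000  # intergenic gap
        for c in coords:
            rows.append((f"cg{probe_no:08d}", chrom, int(c), gene))
            probe_no += 1
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "coordinate", "gene"])


def _probe_mean_layout(
    manifest: pd.DataFrame,
    baseline: Callable[[np.random.Generator, int], np.ndarray] | None,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.Series]:
    """Shared (class-independent) probe means: gene baseline + offsets."""
    genes = manifest["gene"].unique()
    if baseline is None:
        gene_means = pd.Series(rng.uniform(0.2, 0.8, size=len(genes)), index=genes)
    else:
        gene_means = pd.Series(baseline(rng, len(genes)), index=genes)
    offsets = rng.normal(0.0, PROBE_OFFSET_SD, size=len(manifest))
    probe_means = gene_means.loc[manifest["gene"]].to_numpy() + offsets
    return (
        pd.Series(probe_means, index=manifest["probe_id"].to_numpy()),
        gene_means,
    )


def _apply_effect(
    means: np.ndarray, measure: str, size: float, gene_mean: float
) -> np.ndarray:
    """Class-1 probe means for one target gene."""
    n = len(means)
    if measure == "MEAN":
        return means + size
    if measure in ("VAR", "DERIV"):
        zigzag = np.where(np.arange(n) % 2 == 0, 0.5, -0.5) * size
        return means + zigzag
    if measure == "ASYMM":
        # strictly decreasing ramp around the gene baseline
        return gene_mean + np.linspace(size / 2.0, -size / 2.0, n)
    if measure == "DEV":
        mid = (n - 1) / 2.0
        bump = size * (1.0 - np.abs(np.arange(n) - mid) / mid)
        return means + bump
    raise ValueError(f"unknown measure {measure!r}")


def generate_betas(
    manifest: pd.DataFrame,
    n_class0: int = 31,
    n_class1: int = 35,
    effects: Sequence[EffectSpec] = (),
    baseline: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    noise_sd: float = 0.05,
    class_names: tuple[str, str] = DEFAULT_CLASS_NAMES,
    seed: int = 0,
) -> LabeledBetaMatrix:
    """Beta matrix for two sample classes with planted effects.

    Both classes share per-probe expected values except at the target
    genes of the supplied effects, where class-1 means are shifted in
    the way that moves the targeted measure.  Per-probe noise is
    ``N(0, noise_sd)``; values are clipped to [0, 1].  A warning is
    emitted if clipping displaces more than 1% of entries by more than
    three noise standard deviations (effect too large for the scale).
    """
    if n_class0 < 1 or n_class1 < 1:
        raise ValueError("class counts must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    known = set(manifest["gene"])
    for eff in effects:
        unknown = [g for g in eff.target_genes if g not in known]
        if unknown:
            raise ValueError(f"effect targets unknown gene(s): {unknown}")
    targeted: dict[str, EffectSpec] = {}
    for eff in effects:
        for g in eff.target_genes:
            if g in targeted:
                raise ValueError(f"gene {g!r} targeted by more than one effect")
            targeted[g] = eff

    rng = np.random.default_rng(seed)
    probe_means, gene_means = _probe_mean_layout(manifest, baseline, rng)

    n_probes = len(manifest)
    mean0 = probe_means.to_numpy().copy()
    mean1 = mean0.copy()
    probe_noise = np.full(n_probes, noise_sd)

    gene_rows = manifest.groupby("gene", sort=False).indices
    for gene, eff in targeted.items():
        rows = gene_rows[gene]
        mean1[rows] = _apply_effect(
            mean0[rows], eff.measure, eff.effect_size, float(gene_means[gene])
        )
        probe_noise[rows] = eff.noise_sd

    n_total = n_class0 + n_class1
    raw = np.empty((n_probes, n_total))
    raw[:, :n_class0] = mean0[:, None] + rng.normal(
        0.0, probe_noise[:, None], size=(n_probes, n_class0)
    )
    raw[:, n_class0:] = mean1[:, None] + rng.normal(
        0.0, probe_noise[:, None], size=(n_probes, n_class1)
    )
    clipped = np.clip(raw, 0.0, 1.0)
    moved = np.abs(clipped - raw)
    frac_far = float((moved > 3.0 * probe_noise[:, None]).mean())
    if frac_far > 0.01:
        warnings.warn(
            f"clipping displaced {frac_far:.1%} of entries by >3*noise_sd; "
            "planted effects may be too large for the [0,1] scale",
            stacklevel=2,
        )

    width = len(str(n_total))
    samples = [f"S{i:0{width}d}" for i in range(1, n_total + 1)]
    labels = pd.Series(
        [class_names[0]] * n_class0 + [class_names[1]] * n_class1,
        index=samples,
        name="label",
    )
    betas = pd.DataFrame(clipped, index=manifest["probe_id"].to_numpy(), columns=samples)
    betas.index.name = "probe_id"
    return LabeledBetaMatrix(betas=betas, labels=labels)


def generate_gene_sets(
    manifest: pd.DataFrame,
    planted_genes: Sequence[str],
    n_sets: int = 1,
    overlap_fraction: float = 0.5,
    set_size: int = 40,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene sets with a controlled overlap with the planted genes.

    Each set contains ``round(overlap_fraction * set_size)`` planted
    genes and the remainder drawn from non-planted manifest genes.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    genes = list(dict.fromkeys(manifest["gene"]))
    if set_size > len(genes):
        raise ValueError("set_size exceeds number of manifest genes")
    planted = [g for g in dict.fromkeys(planted_genes)]
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in manifest: {sorted(unknown)}")
    n_overlap = round(overlap_fraction * set_size)
    if n_overlap > len(planted):
        raise ValueError(
            f"requested overlap {n_overlap} exceeds {len(planted)} planted genes"
        )
    others = [g for g in genes if g not in set(planted)]
    if set_size - n_overlap > len(others):
        raise ValueError("not enough non-planted genes for the requested set size")

    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        inside = list(rng.choice(planted, size=n_overlap, replace=False))
        outside = list(rng.choice(others, size=set_size - n_overlap, replace=False))
        members = sorted(inside + outside)
        out[f"SET{i:03d}"] = members
    return out
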