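"""Intragene methylation descriptors.

For each gene, the beta values of its CpG probes are ordered by
chromosomal coordinate and summarized by five scalar measures:

* ``MEAN``  — arithmetic mean of the probe betas,
* ``VAR``   — sample variance (denominator ``n - 1``),
* ``DERIV`` — mean absolute difference of consecutive betas,
* ``DEV``   — summed absolute deviation of the profile from the chord
  through its first and last probe (a linearity defect),
* ``ASYMM`` — the fraction of the total absolute consecutive variation
  contributed by decreasing steps, in ``[0, 1]``.

Only genes with at least five probes are retained: several measures need
multiple probes to be defined at all, and a floor on the probe count
stabilizes their values.  A Kendall-concordance diagnostic checks, per
sample, whether the five measures rank the genes in agreement (they
should not — near-redundant measures would add nothing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from intrameth.io import Dataset

logger = logging.getLogger(__name__)

#: canonical measure order used for all matrix columns
MEASURES = ("MEAN", "VAR", "DERIV", "DEV", "ASYMM")

MIN_PROBES = 5

#: separator between gene and measure in flat column names
COLUMN_SEP = "|"


@dataclass(frozen=True)
class GeneProfile:
    """Ordered beta values and coordinates of one gene in one sample."""

    gene: str
    betas: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=float)
        coords = np.asarray(self.coords, dtype=np.int64)
        if betas.shape != coords.shape or betas.ndim != 1:
            raise ValueError("betas and coords must be 1-D of equal length")
        if len(betas) < 2:
            raise ValueError("a profile needs at least 2 probes")
        if np.any(np.diff(coords) <= 0):
            raise ValueError(f"coordinates not strictly increasing for {self.gene}")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return len(self.betas)


def mean_measure(p: GeneProfile) -> float:
    """Arithmetic mean of the probe betas."""
    return float(np.mean(p.betas))


def var_measure(p: GeneProfile) -> float:
    """Sample variance of the probe betas (denominator ``n - 1``)."""
    return float(np.var(p.betas, ddof=1))


def deriv_measure(p: GeneProfile) -> float:
    """Mean absolute difference of consecutive betas."""
    return float(np.mean(np.abs(np.diff(p.betas))))


def dev_measure(p: GeneProfile) -> float:
    """Summed absolute deviation from the endpoint chord.

    The chord passes through ``(coord_1, beta_1)`` and
    ``(coord_n, beta_n)``; the two endpoint terms are identically zero.
    """
    b, c = p.betas, p.coords
    span = c[-1] - c[0]
    if span <= 0:
        raise ValueError(f"zero coordinate span for {p.gene}")
    chord = b[0] + (b[-1] - b[0]) / span * (c - c[0])
    return float(np.sum(np.abs(chord - b)))


def asymm_measure(p: GeneProfile) -> float:
    """Fraction of total consecutive variation due to decreasing steps.

    A constant profile has no directional variation; its asymmetry is
    defined as the neutral value 0.5.
    """
    d = np.diff(p.betas)
    total = np.sum(np.abs(d))
    if total == 0:
        return 0.5
    return float(np.sum(d[d < 0] * -1) / total)


_MEASURE_FUNCS = {
    "MEAN": mean_measure,
    "VAR": var_measure,
    "DERIV": deriv_measure,
    "DEV": dev_measure,
    "ASYMM": asymm_measure,
}


# ---------------------------------------------------------------------------
# gene indexing


@dataclass(frozen=True)
class _GeneBlock:
    """Row indices of one retained gene's probes, coordinate-sorted."""

    gene: str
    rows: np.ndarray  # positional indices into the beta matrix
    coords: np.ndarray


def _index_genes(dataset: Dataset) -> list[_GeneBlock]:
    """Group manifest probes into retained genes.

    Genes annotated on several chromosomes are split into per-chromosome
    pseudo-genes (suffix ``@<chrom>``): coordinate arithmetic across
    chromosomes would be meaningless.  Duplicate (gene, coordinate)
    pairs keep the first occurrence.  Genes with fewer than
    ``MIN_PROBES`` probes after these steps are dropped (logged).
    """
    man = dataset.manifest
    probe_pos = {p: i for i, p in enumerate(dataset.betas.index)}

    multi = man.groupby("gene")["chromosome"].nunique()
    split_genes = set(multi.index[multi > 1])
    if split_genes:
        logger.info("split %d genes spanning multiple chromosomes", len(split_genes))

    effective = man["gene"].where(
        ~man["gene"].isin(split_genes),
        man["gene"].str.cat(man["chromosome"].astype(str), sep="@"),
    )

    blocks: list[_GeneBlock] = []
    n_short = 0
    n_dup_coord = 0
    grouped = (
        pd.DataFrame(
            {
                "gene": effective.to_numpy(),
                "coordinate": man["coordinate"].to_numpy(),
                "probe_id": man["probe_id"].to_numpy(),
            }
        )
        .sort_values(["gene", "coordinate"], kind="mergesort")
        .groupby("gene", sort=True)
    )
    for gene, grp in grouped:
        dedup = grp.drop_duplicates(subset="coordinate", keep="first")
        n_dup_coord += len(grp) - len(dedup)
        if len(dedup) < MIN_PROBES:
            n_short += 1
            continue
        rows = np.array([probe_pos[p] for p in dedup["probe_id"]], dtype=np.intp)
        blocks.append(
            _GeneBlock(str(gene), rows, dedup["coordinate"].to_numpy(np.int64))
        )
    if n_dup_coord:
        logger.info("dropped %d probes at duplicated coordinates", n_dup_coord)
    logger.info(
        "retained %d genes with >=%d probes (%d removed as too short)",
        len(blocks),
        MIN_PROBES,
        n_short,
    )
    if not blocks:
        raise ValueError(f"no gene has >= {MIN_PROBES} probes")
    return blocks


def build_profiles(dataset: Dataset) -> dict[str, dict[str, GeneProfile]]:
    """Per-sample, per-gene ordered beta profiles of the retained genes."""
    blocks = _index_genes(dataset)
    values = dataset.betas.to_numpy(dtype=float)
    out: dict[str, dict[str, GeneProfile]] = {}
    for j, sample in enumerate(dataset.betas.columns):
        out[sample] = {
            blk.gene: GeneProfile(blk.gene, values[blk.rows, j], blk.coords)
            for blk in blocks
        }
    return out


def compute_measure_matrix(
    dataset: Dataset, measures: Sequence[str] = MEASURES
) -> pd.DataFrame:
    """Samples x (gene, measure) feature table.

    Columns are named ``GENE|MEASURE`` and ordered gene-ascending with
    measures in canonical order within each gene.  Computation is
    vectorized per gene over all samples.
    """
    bad = [m for m in measures if m not in _MEASURE_FUNCS]
    if bad:
        raise ValueError(f"unknown measures: {bad}")
    measures = tuple(m for m in MEASURES if m in measures)
    if not measures:
        raise ValueError("no measures requested")

    blocks = _index_genes(dataset)
    values = dataset.betas.to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    for blk in blocks:
        sub = values[blk.rows, :]  # probes x samples
        res = _block_measures(sub, blk.coords, measures)
        for m in measures:
            cols[f"{blk.gene}{COLUMN_SEP}{m}"] = res[m]
    order = [
        f"{blk.gene}{COLUMN_SEP}{m}" for blk in blocks for m in measures
    ]
    return pd.DataFrame(cols, index=dataset.betas.columns.copy())[order]


def _block_measures(
    sub: np.ndarray, coords: np.ndarray, measures: Sequence[str]
) -> dict[str, np.ndarray]:
    """All requested measures for one gene, all samples at once."""
    out: dict[str, np.ndarray] = {}
    d = np.diff(sub, axis=0)
    if "MEAN" in measures:
        out["MEAN"] = sub.mean(axis=0)
    if "VAR" in measures:
        out["VAR"] = sub.var(axis=0, ddof=1)
    if "DERIV" in measures:
        out["DERIV"] = np.abs(d).mean(axis=0)
    if "DEV" in measures:
        span = coords[-1] - coords[0]
        frac = ((coords - coords[0]) / span)[:, None]
        chord = sub[0, :] + (sub[-1, :] - sub[0, :]) * frac
        out["DEV"] = np.abs(chord - sub).sum(axis=0)
    if "ASYMM" in measures:
        total = np.abs(d).sum(axis=0)
        dec = np.where(d < 0, -d, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            a = np.where(total > 0, dec / np.where(total > 0, total, 1.0), 0.5)
        out["ASYMM"] = a
    return out


def split_columns(columns: Iterable[str]) -> pd.DataFrame:
    """Decompose ``GENE|MEASURE`` column names into gene and measure."""
    genes, meas = zip(*(c.rsplit(COLUMN_SEP, 1) for c in columns))
    return pd.DataFrame({"gene": genes, "measure": meas})


# ---------------------------------------------------------------------------
# Kendall concordance diagnostic


def kendall_w(rankings: np.ndarray) -> float:
    """Kendall's coefficient of concordance with the tie correction.

    ``rankings`` is judges x objects of raw scores; each judge's scores
    are converted to average ranks.  Returns W in [0, 1].
    """
    scores = np.asarray(rankings, dtype=float)
    k, m = scores.shape
    if m < 2:
        raise ValueError("need at least 2 objects")
    ranks = np.vstack([stats.rankdata(row) for row in scores])
    col_sums = ranks.sum(axis=0)
    s = np.sum((col_sums - k * (m + 1) / 2.0) ** 2)
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    denom = k**2 * (m**3 - m) - k * tie_term
    if denom <= 0:
        # every judge ranks all objects tied; no information
        return 0.0
    return float(12.0 * s / denom)


def kendall_critical_value(n_judges: int, n_objects: int, alpha: float = 0.05) -> float:
    """Critical W from the chi-square approximation.

    ``k (m - 1) W`` is approximately chi-square with ``m - 1`` degrees
    of freedom under the null of independent rankings.
    """
    chi2 = stats.chi2.ppf(1.0 - alpha, df=n_objects - 1)
    return float(chi2 / (n_judges * (n_objects - 1)))


def kendall_concordance(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-sample concordance of the five measures over the genes.

    For each sample the five measures act as judges, each ranking the
    retained genes by its value (ties get average ranks).  Since the
    number of genes is identical for every sample, a single critical
    value applies dataset-wide.  Returns a frame indexed by sample with
    columns ``W``, ``critical_value`` and ``significant``.
    """
    info = split_columns(matrix.columns)
    present = set(info["measure"])
    missing = set(MEASURES) - present
    if missing:
        raise ValueError(f"concordance needs all five measures; missing {sorted(missing)}")
    genes = sorted(set(info["gene"]))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for concordance")
    crit = kendall_critical_value(len(MEASURES), len(genes), alpha)
    records = []
    for sample in matrix.index:
        scores = np.array(
            [
                [matrix.at[sample, f"{g}{COLUMN_SEP}{m}"] for g in genes]
                for m in MEASURES
            ]
        )
        w = kendall_w(scores)
        records.append({"W": w, "critical_value": crit, "significant": w > crit})
    return pd.DataFrame(records, index=matrix.index.copy())
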