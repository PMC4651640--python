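"""Reading, validating and writing the pipeline's tabular artifacts.

Input formats mirror what a practitioner exports from an Illumina 450K
experiment: a beta-value matrix as TSV (probes x samples), a probe
manifest CSV with ``probe_id, chromosome, coordinate, gene`` columns
(the Illumina ``IlmnID/CHR/MAPINFO/UCSC_RefGene_Name`` fields), a sample
sheet CSV with ``sample_id, label``, and gene sets in GMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: significant digits used when writing beta matrices and measures
FLOAT_DIGITS = 6

MANIFEST_COLUMNS = ["probe_id", "chromosome", "coordinate", "gene"]


@dataclass
class Dataset:
    """A validated, probe/sample-aligned methylation dataset.

    ``betas`` is probes x samples in [0, 1]; ``manifest`` holds one row
    per (probe, gene) assignment; ``labels`` maps sample to class.
    """

    betas: pd.DataFrame
    manifest: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.betas.index.duplicated().any():
            dups = self.betas.index[self.betas.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicated probe identifiers in betas: {dups}")
        if self.betas.columns.duplicated().any():
            dups = self.betas.columns[self.betas.columns.duplicated()][:3].tolist()
            raise ValueError(f"duplicated sample identifiers in betas: {dups}")
        if self.labels.index.duplicated().any():
            raise ValueError("duplicated sample identifiers in sample sheet")
        _check_beta_range(self.betas)
        if not set(self.betas.columns) == set(self.labels.index):
            raise ValueError("sample sets of betas and labels disagree")
        extra = set(self.manifest["probe_id"]) - set(self.betas.index)
        if extra:
            raise ValueError("manifest contains probes absent from betas")

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())


def _check_beta_range(betas: pd.DataFrame) -> None:
    values = betas.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("beta matrix contains non-numeric values")
    bad = ~((values >= 0.0) & (values <= 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value {values[i, j]!r} out of [0,1] at probe "
            f"{betas.index[i]!r}, sample {betas.columns[j]!r}"
        )


def load_dataset(beta_path, manifest_path, samplesheet_path) -> Dataset:
    """Load and align the three tabular inputs.

    Probes and samples are inner-joined across files; dropped counts are
    logged.  Out-of-range or non-numeric betas, duplicated identifiers,
    and an empty probe or sample intersection are errors.
    """
    betas = pd.read_csv(beta_path, sep="\t", index_col=0)
    betas.index = betas.index.astype(str)
    betas.index.name = "probe_id"
    if betas.index.duplicated().any():
        raise ValueError("duplicated probe identifiers in beta matrix")
    for col in betas.columns:
        if not np.issubdtype(betas[col].dtype, np.number):
            raise ValueError(f"non-numeric beta values in sample {col!r}")
    if betas.isna().any().any():
        n_missing = int(betas.isna().any(axis=1).sum())
        logger.warning("dropping %d probes with missing beta values", n_missing)
        betas = betas.dropna(axis=0)
    _check_beta_range(betas)

    manifest = load_manifest(manifest_path)
    sheet = pd.read_csv(samplesheet_path, dtype=str)
    if not {"sample_id", "label"}.issubset(sheet.columns):
        raise ValueError("sample sheet needs 'sample_id' and 'label' columns")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicated sample identifiers in sample sheet")
    labels = sheet.set_index("sample_id")["label"]

    probes = betas.index.intersection(pd.Index(manifest["probe_id"].unique()))
    n_drop_b = len(betas.index) - len(probes)
    n_drop_m = manifest["probe_id"].nunique() - len(probes)
    if n_drop_b:
        logger.info("dropped %d beta probes absent from manifest", n_drop_b)
    if n_drop_m:
        logger.info("dropped %d manifest probes absent from betas", n_drop_m)
    if len(probes) == 0:
        raise ValueError("empty probe intersection of betas and manifest")

    samples = betas.columns.intersection(labels.index)
    n_drop_s = max(len(betas.columns), len(labels)) - len(samples)
    if n_drop_s:
        logger.info("dropped %d samples not shared by betas and sample sheet", n_drop_s)
    if len(samples) == 0:
        raise ValueError("empty sample intersection of betas and sample sheet")

    betas = betas.loc[probes, samples]
    manifest = manifest[manifest["probe_id"].isin(set(probes))].reset_index(drop=True)
    return Dataset(betas=betas, manifest=manifest, labels=labels.loc[samples])


def load_manifest(path) -> pd.DataFrame:
    """Read a probe manifest CSV.

    A probe annotated to several semicolon-separated genes is expanded
    to one row per distinct gene, as in Illumina's
    ``UCSC_RefGene_Name`` convention.
    """
    man = pd.read_csv(path, dtype={"probe_id": str, "chromosome": str, "gene": str})
    missing = set(MANIFEST_COLUMNS) - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    man = man[MANIFEST_COLUMNS].copy()
    man["coordinate"] = man["coordinate"].astype(np.int64)
    man["gene"] = man["gene"].str.split(";")
    man = man.explode("gene", ignore_index=True)
    man["gene"] = man["gene"].str.strip()
    man = man[man["gene"] != ""]
    before = len(man)
    man = man.drop_duplicates(subset=["probe_id", "gene"], ignore_index=True)
    if len(man) < before:
        logger.info("deduplicated %d repeated (probe, gene) rows", before - len(man))
    return man


# ---------------------------------------------------------------------------
# GMT gene sets


def load_gene_sets(gmt_path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered {set name: gene list} mapping.

    Genes duplicated within a set are kept once (logged).  A malformed
    line (fewer than three tab-separated fields) is an error naming the
    line number.
    """
    sets: dict[str, list[str]] = {}
    with open(gmt_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name = fields[0]
            genes, seen = [], set()
            n_dup = 0
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    n_dup += 1
                    continue
                seen.add(g)
                genes.append(g)
            if n_dup:
                logger.warning("set %r: %d duplicated genes kept once", name, n_dup)
            if name in sets:
                raise ValueError(f"duplicated set name {name!r} at line {lineno}")
            sets[name] = genes
    if not sets:
        logger.warning("GMT file %s is empty", gmt_path)
    return sets


def write_gene_sets(sets: dict[str, list[str]], gmt_path, description: str = "synthetic") -> None:
    with open(gmt_path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# writers


def _float_fmt(x: float) -> str:
    return f"{x:.{FLOAT_DIGITS}g}"


def write_betas(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", index_label="probe_id", float_format=f"%.{FLOAT_DIGITS}g")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def write_samplesheet(labels: pd.Series, path) -> None:
    frame = labels.rename("label").rename_axis("sample_id").reset_index()
    frame.to_csv(path, index=False)


def write_measure_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id", float_format=f"%.{FLOAT_DIGITS}g")


def read_measure_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
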