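"""Readers and writers for the standard on-disk formats the pipeline uses:
MatrixMarket / TSV count matrices, covariate CSVs, GMT gene sets, t-score
TSVs and multi-page TIFF scenes with channel metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from gliastat.imaging.types import ImageScene

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_counts_tsv",
    "read_counts_tsv",
    "read_covariates_csv",
    "write_gmt",
    "read_gmt",
    "write_tscores_tsv",
    "read_tscores_tsv",
    "write_scene_tiff",
    "read_scene_tiff",
]


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """counts -> <prefix>.mtx plus <prefix>.genes.tsv / <prefix>.cells.tsv."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    counts.index.to_series().to_csv(prefix.with_suffix(".genes.tsv"), sep="\t", index=False, header=False)
    counts.columns.to_series().to_csv(prefix.with_suffix(".cells.tsv"), sep="\t", index=False, header=False)


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(np.int64)
    genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t", header=None)[0]
    cells = pd.read_csv(prefix.with_suffix(".cells.tsv"), sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=pd.Index(cells, name="cell"))


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    """Covariate CSV with columns cell, disease.status, sex, age, cdr."""
    cov = pd.read_csv(path)
    required = {"cell", "disease.status", "sex", "age", "cdr"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"covariate CSV missing columns: {sorted(missing)}")
    return cov.set_index("cell")


def write_gmt(gene_sets: dict[str, dict | list], path: str | Path) -> None:
    """Gene sets -> GMT (name <tab> description <tab> genes...)."""
    with open(path, "w") as fh:
        for name, rec in gene_sets.items():
            members = rec["members"] if isinstance(rec, dict) else rec
            desc = "enriched" if isinstance(rec, dict) and rec.get("is_enriched") else "na"
            fh.write("\t".join([name, desc, *map(str, members)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_tscores_tsv(tscores: pd.Series, path: str | Path) -> None:
    tscores.rename("t_score").rename_axis("gene").to_csv(path, sep="\t")


def read_tscores_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")["t_score"]


def write_scene_tiff(scene: ImageScene, path: str | Path) -> None:
    """Scene -> multi-page float TIFF, one page per channel; channel names
    and pixel size stored in the TIFF description as JSON."""
    names = sorted(scene.channels)
    stack = np.stack([scene.channels[n].astype(np.float32) for n in names])
    meta = json.dumps({"channels": names, "pixel_size_um": scene.pixel_size})
    tifffile.imwrite(str(path), stack, description=meta)


def read_scene_tiff(path: str | Path, pixel_size: float | None = None) -> ImageScene:
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    names = meta["channels"]
    ps = pixel_size if pixel_size is not None else float(meta["pixel_size_um"])
    return ImageScene(channels={n: stack[i].astype(float) for i, n in enumerate(names)}, pixel_size=ps)
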