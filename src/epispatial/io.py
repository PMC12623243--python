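"""Readers and writers for the on-disk formats used across the pipeline.

Matrices travel as Matrix Market (``.mtx``) with ``features.tsv`` /
``barcodes.tsv`` sidecars in the 10x convention (matrix stored gene x cell);
gene sets as GMT; region annotations as GeoJSON polygons; label images as
ASCII (P2) PGM with 16-bit maxval so every artifact stays plain text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "read_cell_matrix",
    "write_cell_matrix",
    "read_gmt",
    "write_gmt",
    "read_regions_geojson",
    "write_regions_geojson",
    "read_pgm",
    "write_pgm",
]


# ---------------------------------------------------------------- MTX bundles

def write_cell_matrix(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write an AnnData of counts to ``outdir`` as MTX + TSV sidecars.

    ``matrix.mtx`` holds genes x cells (10x orientation); ``features.tsv``
    one gene id per line; ``barcodes.tsv`` the cell ids plus any .obs
    columns (tab-separated, with header).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    obs = adata.obs.copy()
    obs.insert(0, "barcode", adata.obs_names)
    obs.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    return outdir


def read_cell_matrix(indir: str | Path) -> ad.AnnData:
    """Read a matrix bundle written by :func:`write_cell_matrix`."""
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")).T)
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    obs = obs.set_index(obs.columns[0])
    obs.index = obs.index.astype(str)
    obs.index.name = None
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = genes.tolist()
    return adata


# ----------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: [gene, ...]}``.

    The second (description) column is dropped. Signed regulon members may
    be encoded as ``GENE`` or ``GENE[+]`` / ``GENE[-]``; signs are kept in
    the gene strings for the caller to interpret.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
    return path


# ------------------------------------------------------------------- GeoJSON

def write_regions_geojson(
    regions: list[tuple[str, Polygon, str]], path: str | Path
) -> Path:
    """Write ``(class_label, polygon, annotation_id)`` triples as GeoJSON."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"class": label, "annotation_id": ann_id},
        }
        for label, poly, ann_id in regions
    ]
    path = Path(path)
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    return path


def read_regions_geojson(path: str | Path) -> list[tuple[str, Polygon, str]]:
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc["features"]:
        poly = shape(feat["geometry"])
        props = feat.get("properties", {})
        out.append((props["class"], poly, props.get("annotation_id", "")))
    return out


# ----------------------------------------------------------------- ASCII PGM

def write_pgm(image: np.ndarray, path: str | Path, maxval: int = 65535) -> Path:
    """Write an integer label image as plain-text (P2) PGM."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("label image must be 2-D")
    if image.min() < 0 or image.max() > maxval:
        raise ValueError("label values out of PGM range")
    lines = [f"P2", f"{image.shape[1]} {image.shape[0]}", str(maxval)]
    lines += [" ".join(map(str, row)) for row in image.astype(int)]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pgm(path: str | Path) -> np.ndarray:
    tokens: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if tokens[0] != "P2":
        raise ValueError("only ASCII (P2) PGM is supported")
    width, height = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4 : 4 + width * height], dtype=np.int64)
    return data.reshape(height, width)
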