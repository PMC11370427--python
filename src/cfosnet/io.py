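"""Reading and writing of pipeline artifacts.

Canonical tabular dialect is TSV (UTF-8, '.' decimal, full float precision
via repr round-trip); label volumes are NIfTI-1 with the voxel size in the
header; networks export as GraphML (via networkx) and as 3-column edge
lists. Every writer has a matching reader such that read(write(x)) == x.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .candidates import CellCandidates, CountMatrix, LabelVolume
from .connectome import BrainNetwork, CorrelationMatrix


class ParseError(ValueError):
    """A pipeline artifact file is malformed."""


def _read_tsv(path, **kw) -> pd.DataFrame:
    kw.setdefault("float_precision", "round_trip")
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


# -- cell candidates ---------------------------------------------------------

def write_candidates(cands: CellCandidates, path) -> None:
    df = cands.to_frame()
    df.to_csv(path, index=False)


def read_candidates(path, source_spacing=(3.990, 0.943, 0.943)) -> CellCandidates:
    df = pd.read_csv(path)
    required = {"id", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return CellCandidates(
        points=df[["x_um", "y_um", "z_um"]].to_numpy(float),
        ids=df["id"].to_numpy(),
        intensity=df["intensity"].to_numpy(float) if "intensity" in df else None,
        source_spacing=tuple(source_spacing),
    )


# -- label volumes -----------------------------------------------------------

def write_label_volume(vol: LabelVolume, path) -> None:
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.labels.astype(np.int32), affine)
    img.header.set_zooms((vol.voxel_size,) * 3)
    nib.save(img, str(path))


def read_label_volume(path) -> LabelVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ParseError(f"{path}: anisotropic label volume ({zooms})")
    labels = np.asarray(img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise ParseError(f"{path}: non-integer labels")
    origin = tuple(np.asarray(img.affine[:3, 3], float))
    return LabelVolume(
        labels=labels.astype(np.int32), voxel_size=float(zooms[0]), origin=origin
    )


# -- region table ------------------------------------------------------------

def write_region_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_region_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"label", "abbreviation", "name", "tissue_class", "volume_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


# -- count matrix ------------------------------------------------------------

def write_count_matrix(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.values.to_csv(counts_path, sep="\t")
    cm.animal_meta.to_csv(meta_path, sep="\t")


def read_count_matrix(counts_path, meta_path) -> CountMatrix:
    values = _read_tsv(counts_path, index_col=0)
    meta = _read_tsv(meta_path, index_col=0, dtype={"group": str})
    if not values.index.equals(meta.index):
        raise ParseError(
            f"{counts_path} and {meta_path} disagree on the animal index"
        )
    return CountMatrix(
        values=values.astype(int), animal_meta=meta, region_ids=list(values.columns)
    )


# -- correlation matrix ------------------------------------------------------

def write_correlation(c: CorrelationMatrix, path) -> None:
    out = c.values.copy()
    out.index.name = f"n_animals={c.n_animals}"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_correlation(path) -> CorrelationMatrix:
    df = _read_tsv(path, index_col=0)
    tag = df.index.name or ""
    if not tag.startswith("n_animals="):
        raise ParseError(f"{path}: missing n_animals tag in the index header")
    n_animals = int(tag.split("=", 1)[1])
    df.index.name = None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CorrelationMatrix(values=df, n_animals=n_animals)


# -- networks ----------------------------------------------------------------

def write_edge_list(net: BrainNetwork, path) -> None:
    net.edge_list().to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_graphml(net: BrainNetwork, path, node_attrs: pd.DataFrame | None = None) -> None:
    g = net.to_networkx()
    g.graph["nominal_density"] = net.nominal_density
    if node_attrs is not None:
        for col in node_attrs.columns:
            nx.set_node_attributes(g, node_attrs[col].to_dict(), name=str(col))
    nx.write_graphml(g, str(path))


def read_graphml(path) -> BrainNetwork:
    g = nx.read_graphml(str(path))
    nodes = list(g.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v, data in g.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = float(data["r"])
    return BrainNetwork(
        region_ids=tuple(nodes),
        weights=w,
        nominal_density=float(g.graph.get("nominal_density", 0.0) or 0.0),
    )


# -- generic tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


def read_table(path, index_col=0) -> pd.DataFrame:
    return _read_tsv(path, index_col=index_col)
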