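"""Minimal single-resolution .cool reader/writer built on h5py.

Implements just enough of the open2c cooler HDF5 schema (format version 3:
``chroms``, ``bins``, ``pixels``, ``indexes`` groups) to load one
chromosome's balanced dense matrix and to write small fixed-bin files for
tests and demos.  Multi-resolution ``.mcool`` files are addressed with the
usual ``path::/resolutions/<res>`` suffix.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

__all__ = ["read_dense", "write_cool"]


def _open_group(path: str | Path):
    path = str(path)
    subgroup = ""
    if "::" in path:
        path, subgroup = path.split("::", 1)
    f = h5py.File(path, "r")
    grp = f[subgroup] if subgroup else f
    if "pixels" not in grp and "resolutions" in grp:
        # bare .mcool: default to the finest resolution
        res = sorted(int(r) for r in grp["resolutions"])
        grp = grp[f"resolutions/{res[0]}"]
    return f, grp


def read_dense(
    path: str | Path, chromosome: str, balance: bool = False
) -> tuple[np.ndarray, float, int]:
    """Dense symmetric intra-chromosomal matrix for one chromosome.

    Returns ``(matrix, bin_width_kb, start_bp)``.  With ``balance=True``,
    raw counts are scaled by the outer product of the stored ICE weights and
    bins with NaN weight become NaN rows/columns.
    """
    f, grp = _open_group(path)
    try:
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in grp["chroms/name"][:]]
        if chromosome not in names:
            raise ValueError(f"chromosome {chromosome!r} not in {path} ({names})")
        cid = names.index(chromosome)
        offsets = grp["indexes/chrom_offset"][:]
        b0, b1 = int(offsets[cid]), int(offsets[cid + 1])
        n = b1 - b0
        starts = grp["bins/start"][b0:b1]
        ends = grp["bins/end"][b0:b1]
        bin_bp = int(ends[0] - starts[0])

        bin1_offset = grp["indexes/bin1_offset"][:]
        p0, p1 = int(bin1_offset[b0]), int(bin1_offset[b1])
        bin1 = grp["pixels/bin1_id"][p0:p1]
        bin2 = grp["pixels/bin2_id"][p0:p1]
        count = grp["pixels/count"][p0:p1].astype(float)
        keep = (bin2 >= b0) & (bin2 < b1)  # intra-chromosomal only

        dense = np.zeros((n, n))
        i = bin1[keep] - b0
        j = bin2[keep] - b0
        dense[i, j] = count[keep]
        dense[j, i] = count[keep]

        if balance:
            if "weight" not in grp["bins"]:
                raise ValueError(f"{path} has no balancing weights")
            w = grp["bins/weight"][b0:b1].astype(float)
            dense = dense * np.outer(w, w)
        return dense, bin_bp / 1000.0, int(starts[0])
    finally:
        f.close()


def write_cool(
    path: str | Path,
    chromosome: str,
    dense_counts: np.ndarray,
    bin_bp: int = 1000,
    weights: np.ndarray | None = None,
) -> None:
    """Write one chromosome's symmetric count matrix as a minimal .cool."""
    dense_counts = np.asarray(dense_counts)
    n = dense_counts.shape[0]
    iu, ju = np.triu_indices(n)
    mask = dense_counts[iu, ju] != 0
    b1, b2, cnt = iu[mask], ju[mask], dense_counts[iu, ju][mask]
    order = np.lexsort((b2, b1))
    b1, b2, cnt = b1[order], b2[order], cnt[order]

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-type"] = "fixed"
        f.attrs["bin-size"] = bin_bp
        f.attrs["nbins"] = n
        f.attrs["nchroms"] = 1
        f.attrs["nnz"] = len(cnt)
        f.create_dataset("chroms/name", data=np.array([chromosome], dtype="S32"))
        f.create_dataset("chroms/length", data=np.array([n * bin_bp], dtype="i8"))
        starts = bin_bp * np.arange(n, dtype="i8")
        f.create_dataset("bins/chrom", data=np.zeros(n, dtype="i4"))
        f.create_dataset("bins/start", data=starts)
        f.create_dataset("bins/end", data=starts + bin_bp)
        if weights is not None:
            f.create_dataset("bins/weight", data=np.asarray(weights, dtype="f8"))
        f.create_dataset("pixels/bin1_id", data=b1.astype("i8"))
        f.create_dataset("pixels/bin2_id", data=b2.astype("i8"))
        f.create_dataset("pixels/count", data=cnt)
        f.create_dataset("indexes/chrom_offset", data=np.array([0, n], dtype="i8"))
        bin1_offset = np.searchsorted(b1, np.arange(n + 1))
        f.create_dataset("indexes/bin1_offset", data=bin1_offset.astype("i8"))
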