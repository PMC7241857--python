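"""Reading and writing networks as edge-list TSV and MatrixMarket files.

Edge-list format: one ``source<TAB>target<TAB>weight`` line per edge with
0-based indices, meaning *source influences target* (the weight is stored at
``W[target, source]`` under the package's row-equals-inputs convention).  A
header comment records the node count so empty networks round-trip.
MatrixMarket files store ``W`` itself in coordinate format (1-based indices
per the format specification).  Metadata (ensemble family and parameters)
goes to a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.io
import scipy.sparse as sp

from .ensembles import Network, Topology

__all__ = ["write_network", "read_network", "write_metadata", "read_metadata"]


class NetworkParseError(ValueError):
    """Malformed network file; carries the offending line number."""


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("edge-tsv", "mtx"):
            raise ValueError(f"format must be 'edge-tsv' or 'mtx', got {fmt!r}")
        return fmt
    if path.suffix == ".mtx":
        return "mtx"
    if path.suffix in (".tsv", ".txt"):
        return "edge-tsv"
    raise ValueError(f"cannot infer format from suffix {path.suffix!r}; pass fmt=")


def write_network(network, path, fmt: Optional[str] = None, metadata: Optional[dict] = None):
    """Write a Network (or bare weight matrix) to disk losslessly."""
    path = Path(path)
    weights = network.weights if isinstance(network, Network) else sp.csr_matrix(network)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        scipy.io.mmwrite(path, sp.coo_matrix(weights))
    else:
        coo = sp.coo_matrix(weights)
        with open(path, "w") as fh:
            fh.write("# directed edge list: source influences target (weight = W[target, source])\n")
            fh.write(f"# nodes: {weights.shape[0]}\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{j}\t{i}\t{float(w)!r}\n")
    meta = dict(metadata or {})
    if isinstance(network, Network) and network.metadata:
        meta = {**network.metadata, **meta}
    if meta:
        write_metadata(meta, path.with_suffix(path.suffix + ".json"))


def read_network(path, fmt: Optional[str] = None) -> Network:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        weights = sp.csr_matrix(scipy.io.mmread(path))
    else:
        rows, cols, data = [], [], []
        n = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "nodes:" in line:
                        n = int(line.split("nodes:")[1])
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise NetworkParseError(
                        f"{path}:{lineno}: expected 'source<TAB>target<TAB>weight', got {line!r}"
                    )
                try:
                    src, tgt, w = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
                rows.append(tgt)
                cols.append(src)
                data.append(w)
        if n is None:
            n = max(max(rows, default=-1), max(cols, default=-1)) + 1
        weights = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = read_metadata(sidecar) if sidecar.exists() else {}
    topology = Topology((weights != 0).astype(np.int8))
    return Network(weights=weights, topology=topology, metadata=meta)


def write_metadata(metadata: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, default=float)
        fh.write("\n")


def read_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
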