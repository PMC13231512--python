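"""Chunked on-disk store for pair x sample dPCC tensors.

At full scale the pair dimension reaches hundreds of millions, so the
tensor is written in pair-order chunks that bound memory. Each chunk is
a TSV (rna_id, mirna_id, then one column per tumour sample) and a
``manifest.json`` records chunk offsets, tumour ids, the normal-cohort
size and creation parameters. Reads reassemble the tensor and are
round-trip exact (floats serialized with repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .engine import DeltaPccTensor

__all__ = ["DeltaStoreWriter", "write_store", "read_store"]

MANIFEST = "manifest.json"


class DeltaStoreWriter:
    """Write dPCC blocks to ``directory`` in ascending pair order."""

    def __init__(self, directory: str | Path, tumour_ids: list[str], n_normal: int, params: dict | None = None):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.tumour_ids = list(tumour_ids)
        self.n_normal = int(n_normal)
        self.params = dict(params or {})
        self._chunks: list[dict] = []
        self._next_start = 0
        self._closed = False

    def write_block(self, block: DeltaPccTensor, start: int) -> None:
        """Append a block whose first pair has global index ``start``."""
        if self._closed:
            raise RuntimeError("store already closed")
        if block.tumour_ids != self.tumour_ids:
            raise ValueError("block tumour ids do not match the store")
        if start != self._next_start:
            raise ValueError(
                f"out-of-order block: expected start {self._next_start}, got {start}"
            )
        idx = len(self._chunks)
        path = self.directory / f"chunk-{idx:05d}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rna_id\tmirna_id\t" + "\t".join(self.tumour_ids) + "\n")
            for (rid, mid), row in zip(block.pair_index, block.values):
                fh.write(rid + "\t" + mid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        self._chunks.append({"file": path.name, "start": start, "n_pairs": len(block.pair_index)})
        self._next_start = start + len(block.pair_index)

    def close(self) -> None:
        manifest = {
            "format": "deltapcc-store-v1",
            "tumour_ids": self.tumour_ids,
            "n_normal": self.n_normal,
            "n_pairs": self._next_start,
            "chunks": self._chunks,
            "params": self.params,
        }
        with open(self.directory / MANIFEST, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        self._closed = True

    def __enter__(self) -> "DeltaStoreWriter":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()


def write_store(directory: str | Path, tensor: DeltaPccTensor, n_normal: int,
                chunk_size: int = 1_000_000, params: dict | None = None) -> None:
    """Write a whole tensor, chunked into at most ``chunk_size`` pairs."""
    with DeltaStoreWriter(directory, tensor.tumour_ids, n_normal, params) as w:
        for start in range(0, len(tensor.pair_index), chunk_size):
            stop = min(start + chunk_size, len(tensor.pair_index))
            block = DeltaPccTensor(
                tensor.values[start:stop], tensor.pair_index[start:stop], tensor.tumour_ids
            )
            w.write_block(block, start)


def read_store(directory: str | Path) -> tuple[DeltaPccTensor, dict]:
    """Reassemble a stored tensor; returns (tensor, manifest)."""
    directory = Path(directory)
    mpath = directory / MANIFEST
    if not mpath.exists():
        raise FileNotFoundError(f"no {MANIFEST} in {directory}")
    manifest = json.loads(mpath.read_text())
    tumour_ids = manifest["tumour_ids"]
    pair_index: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for chunk in manifest["chunks"]:
        path = directory / chunk["file"]
        if not path.exists():
            raise FileNotFoundError(f"missing chunk file {path.name}")
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[2:] != tumour_ids:
                raise ValueError(f"chunk {path.name} header disagrees with manifest")
            rows = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                pair_index.append((fields[0], fields[1]))
                rows.append([float(v) for v in fields[2:]])
        got = len(rows)
        if got != chunk["n_pairs"]:
            raise ValueError(f"chunk {path.name}: expected {chunk['n_pairs']} pairs, found {got}")
        blocks.append(np.array(rows, dtype=float).reshape(got, len(tumour_ids)))
    values = np.concatenate(blocks, axis=0) if blocks else np.empty((0, len(tumour_ids)))
    return DeltaPccTensor(values, pair_index, tumour_ids), manifest
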