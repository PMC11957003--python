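"""Dataset curation: filtering candidate map/model pairs and resolution splits.

A manifest is a TSV table with columns ``map_id``, ``model_id``,
``reported_resolution`` (absent values encoded as empty strings). The filters
mirror how a benchmark corpus is assembled from public archives:

1. drop entries without an atomic model,
2. drop entries without a reported resolution, or outside the accepted
   resolution band (default 1-4 Angstrom, inclusive),
3. de-duplicate maps sharing a model, keeping the best (smallest) resolution
   (ties broken by lexicographic map id).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ManifestEntry",
    "ManifestError",
    "read_manifest",
    "write_manifest",
    "filter_manifest",
    "split_by_resolution",
]


class ManifestError(ValueError):
    """Raised for structurally invalid manifests (e.g. duplicate map ids)."""


@dataclass(frozen=True)
class ManifestEntry:
    """One candidate map/model pair."""

    map_id: str
    model_id: str | None = None
    reported_resolution: float | None = None


def read_manifest(path: str | os.PathLike) -> list[ManifestEntry]:
    """Read a TSV manifest with a header row into entries."""
    df = pd.read_csv(path, sep="\t", dtype={"map_id": str, "model_id": str})
    required = {"map_id", "model_id", "reported_resolution"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest is missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        model = row.model_id
        model = None if (model is None or (isinstance(model, float) and math.isnan(model)) or str(model).strip() == "") else str(model)
        res = row.reported_resolution
        res = None if (res is None or (isinstance(res, float) and math.isnan(res))) else float(res)
        entries.append(ManifestEntry(str(row.map_id), model, res))
    return entries


def write_manifest(entries: list[ManifestEntry], path: str | os.PathLike) -> None:
    """Write entries back to TSV (absent fields as empty strings)."""
    df = pd.DataFrame(
        {
            "map_id": [e.map_id for e in entries],
            "model_id": [e.model_id or "" for e in entries],
            "reported_resolution": [
                "" if e.reported_resolution is None else e.reported_resolution
                for e in entries
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_manifest(
    entries: list[ManifestEntry],
    min_res: float = 1.0,
    max_res: float = 4.0,
) -> tuple[list[ManifestEntry], dict[str, int]]:
    """Apply the curation filters; returns survivors and per-rule drop counts.

    Counts are reported under ``no_model``, ``no_resolution``,
    ``resolution_out_of_range`` and ``redundant_model``; their sum plus the
    survivor count equals the input count. Entries are tested against the
    rules in that order, so each dropped entry is counted once.

    Raises
    ------
    ManifestError
        If two entries share a map id.
    """
    ids = [e.map_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ManifestError(f"duplicate map_id(s) in manifest: {dupes}")

    counts = {
        "no_model": 0,
        "no_resolution": 0,
        "resolution_out_of_range": 0,
        "redundant_model": 0,
    }
    staged: list[ManifestEntry] = []
    for e in entries:
        if e.model_id is None:
            counts["no_model"] += 1
        elif e.reported_resolution is None:
            counts["no_resolution"] += 1
        elif not (min_res <= e.reported_resolution <= max_res):
            counts["resolution_out_of_range"] += 1
        else:
            staged.append(e)

    best: dict[str, ManifestEntry] = {}
    for e in staged:
        prev = best.get(e.model_id)  # type: ignore[arg-type]
        if prev is None:
            best[e.model_id] = e  # type: ignore[index]
            continue
        counts["redundant_model"] += 1
        better = (e.reported_resolution, e.map_id) < (
            prev.reported_resolution,
            prev.map_id,
        )
        if better:
            best[e.model_id] = e  # type: ignore[index]
    # preserve input order of the kept entries
    kept_ids = {e.map_id for e in best.values()}
    survivors = [e for e in staged if e.map_id in kept_ids]
    return survivors, counts


def split_by_resolution(
    entries: list[ManifestEntry],
    bin_edges,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, list[ManifestEntry]]:
    """Assign entries to train/val/test within resolution bins.

    Stratifying by resolution keeps each split's difficulty distribution
    comparable. Within each bin, entries are shuffled deterministically
    (``seed``) and allocated to the splits by largest-remainder rounding of
    ``fractions``. Entries without a resolution, or outside every bin, raise.

    Raises
    ------
    ValueError
        If fractions do not sum to 1, or an entry falls in no bin.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    edges = np.asarray(list(bin_edges), dtype=float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be increasing with at least two values")

    bins: dict[int, list[ManifestEntry]] = {i: [] for i in range(len(edges) - 1)}
    for e in entries:
        if e.reported_resolution is None:
            raise ValueError(f"entry {e.map_id} has no resolution; cannot stratify")
        # last bin is closed on the right
        b = int(np.digitize(e.reported_resolution, edges, right=False)) - 1
        if b == len(edges) - 1 and e.reported_resolution == edges[-1]:
            b -= 1
        if not 0 <= b < len(edges) - 1:
            raise ValueError(
                f"entry {e.map_id} resolution {e.reported_resolution} outside bins"
            )
        bins[b].append(e)

    rng = np.random.default_rng(seed)
    splits: dict[str, list[ManifestEntry]] = {"train": [], "val": [], "test": []}
    for b in sorted(bins):
        members = bins[b]
        if not members:
            warnings.warn(f"resolution bin {b} is empty; skipped", stacklevel=2)
            continue
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        sizes = _largest_remainder(len(members), fractions)
        pos = 0
        for name, size in zip(("train", "val", "test"), sizes):
            splits[name].extend(shuffled[pos : pos + size])
            pos += size
    return splits


def _largest_remainder(n: int, fractions) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(math.floor(x)) for x in exact]
    rem = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - sizes[i],
                   reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes
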