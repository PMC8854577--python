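"""Nucleosome occupancy features for guides.

A per-base occupancy track (e.g. MNase-seq coverage) is averaged over each
guide's target locus (spacer plus PAM by default) and normalized to [0, 1] by
dividing by the highest per-guide average in the scored set, giving the
scalar chromatin feature consumed by the activity model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome, NUCLEASES, BoundsError, context_flanks


@dataclass
class OccupancyTrack:
    """Per-base non-negative coverage, one array per chromosome."""

    values: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if (v < 0).any():
                raise ValueError(f"negative occupancy on {chrom}")
            self.values[chrom] = v

    def __getitem__(self, chrom):
        return self.values[chrom]

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        v = self.values[chrom]
        if start < 0 or end > len(v) or start >= end:
            raise BoundsError(f"[{start}, {end}) outside occupancy track for "
                              f"{chrom} (length {len(v)})")
        return float(v[start:end].mean())


def read_bedgraph(path, lengths: dict[str, int] | None = None) -> OccupancyTrack:
    """Load a 4-column bedGraph (chrom, start, end, value; 0-based half-open).

    Bases not covered by any interval default to 0.  ``lengths`` fixes the
    per-chromosome array sizes; otherwise the maximum end coordinate is used.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["chrom", "start", "end", "value"])
    values = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        n = lengths[chrom] if lengths else int(sub["end"].max())
        arr = np.zeros(n)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[int(s):int(e)] = v
        values[str(chrom)] = arr
    if lengths:
        for chrom, n in lengths.items():
            values.setdefault(chrom, np.zeros(n))
    return OccupancyTrack(values)


def read_wig(path, lengths: dict[str, int] | None = None) -> OccupancyTrack:
    """Load a fixedStep WIG track (1-based starts, per-line values)."""
    values: dict[str, list] = {}
    chrom, pos, step = None, 0, 1
    entries: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
                entries.setdefault(chrom, {})
            else:
                if chrom is None:
                    raise ValueError(f"{path}: data line before fixedStep header")
                entries[chrom][pos] = float(line)
                pos += step
    out = {}
    for chrom, d in entries.items():
        n = lengths[chrom] if lengths else max(d) + 1
        arr = np.zeros(n)
        for p, v in d.items():
            arr[p] = v
        out[chrom] = arr
    return OccupancyTrack(out)


def write_bedgraph(track: OccupancyTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, v in track.values.items():
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def target_interval(guide, nuclease: str, mode: str = "spacer_pam") -> tuple[int, int]:
    """Reference interval scored for a guide: spacer+PAM (default), spacer
    only, or the full model context window."""
    spec = NUCLEASES[nuclease]
    sp, pl = spec["spacer_len"], spec["pam_len"]
    s = guide.start
    if mode == "spacer":
        return s, s + sp
    if mode == "spacer_pam":
        pam_right = (guide.strand == "+") == (spec["pam_side"] == "3prime")
        return (s, s + sp + pl) if pam_right else (s - pl, s + sp)
    if mode == "context":
        a, b = target_interval(guide, nuclease, "spacer_pam")
        up, down = context_flanks(nuclease, spec["context_len"])
        return (a - up, b + down) if guide.strand == "+" else (a - down, b + up)
    raise ValueError(f"unknown interval mode {mode!r}")


def guide_mean_occupancy(track: OccupancyTrack, guide, nuclease: str = "cas12a",
                         mode: str = "spacer_pam") -> float:
    """Arithmetic mean of per-base occupancy over the guide's target locus."""
    a, b = target_interval(guide, nuclease, mode)
    return track.mean_over(guide.chrom, a, b)


def normalize_occupancy(means: pd.Series | dict) -> pd.Series:
    """Scale per-guide mean occupancies to [0, 1] by the set maximum."""
    s = pd.Series(means, dtype=float)
    if len(s) == 0:
        raise ValueError("empty occupancy set")
    if (s < 0).any():
        raise ValueError("occupancy means must be non-negative")
    top = s.max()
    if top == 0:
        warnings.warn("all occupancy means are zero; returning zeros")
        return s
    return s / top


def occupancy_for_library(track: OccupancyTrack, library, nuclease: str = "cas12a",
                          mode: str = "spacer_pam") -> pd.Series:
    """Normalized [0, 1] occupancy for every targeting guide in a library.
    Non-targeting guides score 0 (no locus)."""
    raw = {}
    for g in library:
        raw[g.guide_id] = (guide_mean_occupancy(track, g, nuclease, mode)
                           if g.targeting else np.nan)
    s = pd.Series(raw)
    targeting = s.dropna()
    norm = normalize_occupancy(targeting) if len(targeting) else targeting
    return norm.reindex(s.index).fillna(0.0)


def write_occupancy_tsv(occ: pd.Series, path) -> None:
    occ.rename("occupancy").rename_axis("guide_id").to_csv(path, sep="\t")
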