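"""Screen quantification: exact-match counting, normalization, cutting scores.

A guide's cutting score (CS) is the log2 ratio of its normalized abundance in
the no-nuclease control to its normalized abundance in the nuclease-expressing
sample after the growth screen, so higher CS = more depletion = more active
guide.  Order of operations: pseudo-count of 1 on zero raw counts, per-sample
normalization to relative abundance, averaging of normalized abundances across
biological replicates, then a single log2 ratio.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

PSEUDOCOUNT = 1


@dataclass
class ReadCountTable:
    """Raw counts (guides x samples) plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``condition``
    ('control' or 'treatment'), ``replicate`` and optionally ``timepoint``.
    ``unmatched`` tallies reads that matched no spacer (FASTQ path only).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unmatched: dict | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        bad = set(self.samples["condition"]) - {"control", "treatment"}
        if bad:
            raise ValueError(f"unknown condition(s): {sorted(bad)}")

    def columns_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns
                if self.samples.loc[s, "condition"] == condition]


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def count_exact_matches(fastq_paths: dict[str, str], library,
                        samples: pd.DataFrame, offset: int = 0,
                        scan: bool = False) -> ReadCountTable:
    """Count reads per guide by exact spacer match at a fixed read offset.

    ``fastq_paths`` maps sample id -> FASTQ(.gz) path.  With ``scan=True`` the
    spacer may sit anywhere in the read (slower; first match wins).  Each read
    increments at most one guide; reads matching no spacer are tallied.
    """
    spacer_to_guide = {}
    for g in library:
        spacer_to_guide.setdefault(g.spacer, g.guide_id)
    lengths = {len(g.spacer) for g in library}
    if len(lengths) != 1:
        raise ValueError("library mixes spacer lengths; count per-nuclease")
    L = lengths.pop()
    guide_ids = [g.guide_id for g in library]
    counts = pd.DataFrame(0, index=guide_ids, columns=list(fastq_paths),
                          dtype=int)
    unmatched = {}
    for sample, path in fastq_paths.items():
        n_un = n_total = 0
        with _open_maybe_gzip(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                n_total += 1
                read = str(rec.seq).upper()
                gid = spacer_to_guide.get(read[offset:offset + L])
                if gid is None and scan:
                    for i in range(len(read) - L + 1):
                        gid = spacer_to_guide.get(read[i:i + L])
                        if gid is not None:
                            break
                if gid is None:
                    n_un += 1
                else:
                    counts.loc[gid, sample] += 1
        if n_total == 0:
            warnings.warn(f"sample {sample!r}: empty FASTQ, all-zero counts")
        unmatched[sample] = n_un
    return ReadCountTable(counts, samples.copy(), unmatched)


def normalize_counts(table: ReadCountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1).

    A pseudo-count of 1 replaces any raw count of zero before normalization,
    so downstream log ratios are always finite.
    """
    counts = table.counts if isinstance(table, ReadCountTable) else table
    zero_samples = [c for c in counts.columns if counts[c].sum() == 0]
    if zero_samples:
        raise ValueError(f"sample(s) with zero total reads: {zero_samples}")
    adj = counts.where(counts > 0, PSEUDOCOUNT).astype(float)
    return adj / adj.sum(axis=0)


def cutting_score(control_norm: pd.DataFrame,
                  treatment_norm: pd.DataFrame) -> pd.DataFrame:
    """Per-guide CS = log2(mean control abundance / mean treatment abundance).

    Inputs are normalized-abundance tables with one column per biological
    replicate.  Replicates are averaged per condition before the ratio; the
    across-replicate standard deviation of each condition's abundances is
    reported alongside.
    """
    control_norm = pd.DataFrame(control_norm)
    treatment_norm = pd.DataFrame(treatment_norm)
    only_c = control_norm.index.difference(treatment_norm.index)
    only_t = treatment_norm.index.difference(control_norm.index)
    if len(only_c) or len(only_t):
        example = (list(only_c) + list(only_t))[0]
        raise ValueError(f"guide {example!r} present in only one condition")
    treatment_norm = treatment_norm.loc[control_norm.index]
    mean_c = control_norm.mean(axis=1)
    mean_t = treatment_norm.mean(axis=1)
    cs = np.log2(mean_c / mean_t)
    out = pd.DataFrame({
        "cs": cs,
        "mean_control": mean_c,
        "mean_treatment": mean_t,
        "sd_control": control_norm.std(axis=1, ddof=1) if control_norm.shape[1] > 1 else 0.0,
        "sd_treatment": treatment_norm.std(axis=1, ddof=1) if treatment_norm.shape[1] > 1 else 0.0,
        "n_control": control_norm.shape[1],
        "n_treatment": treatment_norm.shape[1],
    })
    out.index.name = "guide_id"
    return out


def cutting_scores_from_table(table: ReadCountTable) -> pd.DataFrame:
    """Normalize a raw count table and compute CS from its control/treatment
    replicate columns."""
    norm = normalize_counts(table)
    ctrl = table.columns_for("control")
    trt = table.columns_for("treatment")
    if not ctrl or not trt:
        raise ValueError("need at least one control and one treatment sample")
    return cutting_score(norm[ctrl], norm[trt])


def control_summary(cs_table: pd.DataFrame, nontargeting_ids,
                    bins: int = 50) -> dict:
    """Mean, sd and histogram of the non-targeting (control-guide) CS
    population; anchors the inactive end of the score scale."""
    ids = [i for i in nontargeting_ids if i in cs_table.index]
    if len(ids) < 2:
        raise ValueError("need at least 2 non-targeting guides with scores")
    vals = cs_table.loc[ids, "cs"].to_numpy(dtype=float)
    hist, edges = np.histogram(vals, bins=bins)
    return {"n": len(vals), "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "histogram": hist, "bin_edges": edges}


def write_counts_tsv(table: ReadCountTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "guide_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path, samples: pd.DataFrame) -> ReadCountTable:
    counts = pd.read_csv(path, sep="\t", index_col="guide_id")
    return ReadCountTable(counts, samples)


def write_cs_tsv(cs_table: pd.DataFrame, path) -> None:
    cs_table.to_csv(path, sep="\t")


def read_cs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="guide_id")
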