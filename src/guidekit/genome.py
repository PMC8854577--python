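"""Genome and annotation I/O, k-mer extraction, context windows, one-hot encoding.

Conventions used throughout the package:

* coordinates are 0-based, half-open;
* spacers are stored 5'->3' on the targeted strand; ``start`` is the leftmost
  reference coordinate of the spacer interval;
* the one-hot row order is A, C, G, T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: spacer and PAM lengths per nuclease; PAM side relative to the spacer.
NUCLEASES = {
    "cas9": {"spacer_len": 20, "pam_len": 3, "pam_side": "3prime", "context_len": 28},
    "cas12a": {"spacer_len": 25, "pam_len": 4, "pam_side": "5prime", "context_len": 32},
}


class FastaParseError(ValueError):
    pass


class EncodeError(ValueError):
    pass


class BoundsError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of chromosomes over the alphabet {A, C, G, T, N}."""

    sequences: dict[str, str]
    source: str = ""

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not seq:
                raise FastaParseError(f"chromosome {name!r} is empty")
            up = seq.upper()
            bad = set(up) - set("ACGTN")
            if bad:
                raise FastaParseError(
                    f"chromosome {name!r} contains invalid symbol(s): {sorted(bad)}")
            self.sequences[name] = up

    def __contains__(self, chrom):
        return chrom in self.sequences

    def __getitem__(self, chrom) -> str:
        return self.sequences[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand slice with explicit bounds checking."""
        L = self.length(chrom)
        if start < 0 or end > L or start >= end:
            raise BoundsError(
                f"[{start}, {end}) outside chromosome {chrom!r} of length {L}")
        return self.sequences[chrom][start:end]


@dataclass
class GeneModel:
    """A gene as a sorted list of non-overlapping CDS intervals (0-based, half-open)."""

    gene_id: str
    chrom: str
    intervals: list[tuple[int, int]]
    strand: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.intervals = sorted((int(a), int(b)) for a, b in self.intervals)
        for (a, b) in self.intervals:
            if a >= b:
                raise ValueError(f"empty interval [{a}, {b}) in gene {self.gene_id}")
        for (_, b1), (a2, _) in zip(self.intervals, self.intervals[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping CDS intervals in gene {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]

    def cds_sequence(self, genome: Genome) -> str:
        s = "".join(genome.slice(self.chrom, a, b) for a, b in self.intervals)
        return reverse_complement(s) if self.strand == "-" else s


def read_fasta(path) -> Genome:
    """Parse a FASTA file into a :class:`Genome` (case-normalized, validated)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} is empty"
                                  f" (line {_find_header_line(path, rec.id)})")
        bad = set(seq) - set("ACGTN")
        if bad:
            line = _find_bad_symbol_line(path, bad)
            raise FastaParseError(
                f"{path}: record {rec.id!r} contains invalid symbol(s) "
                f"{sorted(bad)} (first at line {line})")
        sequences[rec.id] = seq
    return Genome(sequences, source=str(path))


def _find_header_line(path, rec_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0:1] == [rec_id]:
                return i
    return -1


def _find_bad_symbol_line(path, bad: set) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.startswith(">") and bad & set(line.strip().upper()):
                return i
    return -1


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in genome.sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_gff3(path) -> list[GeneModel]:
    """Read gene models (CDS features grouped by parent gene) from GFF3."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: dict[str, GeneModel] = {}
    buckets: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID") or ["?"]
        gid = parents[0].split(":")[-1]
        b = buckets.setdefault(gid, {"chrom": cds.seqid, "strand": cds.strand,
                                     "intervals": []})
        b["intervals"].append((cds.start - 1, cds.end))  # GFF3 is 1-based inclusive
    for gid, b in buckets.items():
        genes[gid] = GeneModel(gid, b["chrom"], b["intervals"], b["strand"])
    return list(genes.values())


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(f"{g.chrom}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for i, (a, b) in enumerate(g.intervals):
                fh.write(f"{g.chrom}\t.\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t"
                         f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# k-mer extraction

def extract_kmers(genome: Genome, k: int, step: int = 1,
                  strand_mode: str = "forward") -> Iterator[str]:
    """Yield k-mers with a sliding window; windows containing N are skipped.

    Forward mode yields ⌊(L−k)/step⌋+1 windows per N-free chromosome; ``both``
    additionally yields the reverse complement of each window.
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if k > min(genome.length(c) for c in genome.chromosomes):
        warnings.warn(f"k={k} exceeds the shortest chromosome; "
                      "some chromosomes yield no k-mers")
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        for i in range(0, len(seq) - k + 1, step):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            yield kmer
            if strand_mode == "both":
                yield reverse_complement(kmer)


def count_kmers(genome: Genome, k: int, step: int = 1,
                strand_mode: str = "forward") -> tuple[int, int]:
    """Count (kept, skipped-for-N) windows without materializing them.

    Uses a cumulative-sum N mask per chromosome, so it is fast on
    multi-megabase genomes.
    """
    if k < 1 or step < 1:
        raise ValueError("k and step must be >= 1")
    kept = skipped = 0
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        L = len(seq)
        if L < k:
            continue
        starts = np.arange(0, L - k + 1, step)
        is_n = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
        if is_n.any():
            cum = np.concatenate(([0], np.cumsum(is_n)))
            has_n = (cum[starts + k] - cum[starts]) > 0
            n_skip = int(has_n.sum())
        else:
            n_skip = 0
        kept += len(starts) - n_skip
        skipped += n_skip
    if strand_mode == "both":
        kept, skipped = 2 * kept, 2 * skipped
    return kept, skipped


# ---------------------------------------------------------------------------
# one-hot encoding

def one_hot(seq: str) -> np.ndarray:
    """Encode an ACGT string as a 4 x n binary matrix (rows A, C, G, T)."""
    idx = np.empty(len(seq), dtype=np.int64)
    for i, b in enumerate(seq):
        j = _BASE_INDEX.get(b)
        if j is None:
            raise EncodeError(f"cannot one-hot encode symbol {b!r} at position {i}")
        idx[i] = j
    m = np.zeros((4, len(seq)), dtype=np.int8)
    m[idx, np.arange(len(seq))] = 1
    return m


def one_hot_batch(seqs: Iterable[str]) -> np.ndarray:
    """Stack one-hot matrices into an (N, 4, n) float array."""
    mats = [one_hot(s) for s in seqs]
    return np.stack(mats).astype(float)


def decode_one_hot(matrix: np.ndarray) -> str:
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != 4 or not np.all(m.sum(axis=0) == 1):
        raise EncodeError("not a valid 4 x n one-hot matrix")
    return "".join(BASES[i] for i in m.argmax(axis=0))


# ---------------------------------------------------------------------------
# context windows

def context_flanks(nuclease: str, length: int) -> tuple[int, int]:
    """Upstream/downstream flank widths for a total context of ``length`` bp.

    The core (spacer + PAM) is fixed per nuclease; extra bases are split with
    the smaller share upstream (2 up / 3 down for the 28 bp Cas9 window,
    1 up / 2 down for the 32 bp Cas12a window).
    """
    spec = NUCLEASES[nuclease]
    core = spec["spacer_len"] + spec["pam_len"]
    if length < core:
        raise ValueError(f"context length {length} shorter than spacer+PAM ({core})")
    extra = length - core
    return extra // 2, extra - extra // 2


def context_window(genome: Genome, guide, nuclease: str,
                   length: int | None = None) -> str:
    """Fixed-length sequence context around a guide, 5'->3' on the targeted strand.

    Layouts: Cas9 -> [up][spacer 20][PAM 3][down]; Cas12a -> [up][PAM 4]
    [spacer 25][down].  Minus-strand guides are returned reverse-complemented.
    """
    spec = NUCLEASES[nuclease]
    if length is None:
        length = spec["context_len"]
    up, down = context_flanks(nuclease, length)
    sp, pl = spec["spacer_len"], spec["pam_len"]
    s = guide.start
    if spec["pam_side"] == "3prime":  # Cas9: PAM follows the spacer
        if guide.strand == "+":
            lo, hi = s - up, s + sp + pl + down
        else:
            lo, hi = s - pl - down, s + sp + up
    else:  # Cas12a: PAM precedes the spacer
        if guide.strand == "+":
            lo, hi = s - pl - up, s + sp + down
        else:
            lo, hi = s - down, s + sp + pl + up
    window = genome.slice(guide.chrom, lo, hi)
    if guide.strand == "-":
        window = reverse_complement(window)
    if "N" in window:
        raise EncodeError(f"guide {getattr(guide, 'guide_id', '?')}: "
                          "context window contains N")
    return window
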