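"""sgRNA library design: PAM scanning, candidate enumeration, uniqueness
filtering, per-gene selection, and non-targeting controls.

The Cas12a path mirrors the screen's design rules: 25-nt spacers next to a
TTTV PAM found on both strands of each CDS, filtered so that the 14-nt
PAM-proximal seed occurs exactly once among all genome-wide TTTN candidates,
then picked 5'->3' along the CDS with strand alternation.  Non-targeting
controls are random spacers whose first 10 nt occur nowhere in the genome on
either strand.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (Genome, GeneModel, NUCLEASES, reverse_complement,
                     context_window)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_PAMS = {"cas9": "NGG", "cas12a": "TTTV"}
#: genome-wide patterns used when indexing candidate multiplicity
INDEX_PAMS = {"cas9": "NGG", "cas12a": "TTTN"}


def iupac_to_regex(pattern: str) -> str:
    try:
        return "".join("[" + IUPAC[c] + "]" if len(IUPAC[c]) > 1 else IUPAC[c]
                       for c in pattern.upper())
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code {e.args[0]!r} in pattern {pattern!r}")


def reverse_complement_iupac(pattern: str) -> str:
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass
class GuideRecord:
    """A spacer with its PAM, locus and target gene.

    ``start`` is the leftmost reference coordinate of the spacer interval;
    ``spacer`` reads 5'->3' on the targeted strand.  Non-targeting controls
    carry ``chrom=None``, ``start=-1``, ``strand='.'``.
    """

    guide_id: str
    spacer: str
    pam: str
    chrom: str | None
    start: int
    strand: str
    gene_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        for name, s in (("spacer", self.spacer), ("pam", self.pam)):
            if set(s) - set("ACGT"):
                raise ValueError(f"{name} {s!r} contains non-ACGT symbols")

    @property
    def targeting(self) -> bool:
        return self.chrom is not None


def find_pam_sites(genome: Genome, pam_pattern: str,
                   both_strands: bool = True) -> list[tuple[str, int, str]]:
    """All occurrences of an IUPAC PAM pattern; overlapping matches included.

    Positions are 0-based leftmost plus-strand coordinates of the matched
    window; for minus-strand hits the window read 5'->3' on the minus strand
    matches the pattern.
    """
    fwd = re.compile("(?=" + iupac_to_regex(pam_pattern) + ")")
    patterns = [(fwd, "+")]
    if both_strands:
        rev = re.compile("(?=" + iupac_to_regex(reverse_complement_iupac(pam_pattern)) + ")")
        patterns.append((rev, "-"))
    hits = []
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        for rx, strand in patterns:
            hits.extend((chrom, m.start(), strand) for m in rx.finditer(seq))
    return hits


def _candidates_in_interval(genome: Genome, chrom: str, a: int, b: int,
                            nuclease: str, pam_pattern: str, gene_id: str):
    """Spacer+PAM sites fully inside [a, b) on both strands."""
    spec = NUCLEASES[nuclease]
    sp, pl = spec["spacer_len"], spec["pam_len"]
    seq = genome[chrom]
    region = seq[a:b]
    fwd = re.compile("(?=" + iupac_to_regex(pam_pattern) + ")")
    rev = re.compile("(?=" + iupac_to_regex(reverse_complement_iupac(pam_pattern)) + ")")
    out = []
    for m in fwd.finditer(region):
        p = a + m.start()  # PAM start, plus strand
        if spec["pam_side"] == "3prime":
            s0, s1 = p - sp, p  # Cas9: spacer precedes NGG
        else:
            s0, s1 = p + pl, p + pl + sp  # Cas12a: spacer follows TTTV
        if s0 < a or s1 > b or p + pl > b:
            continue
        spacer, pam = seq[s0:s1], seq[p:p + pl]
        if "N" in spacer or "N" in pam:
            continue
        out.append(GuideRecord("", spacer, pam, chrom, s0, "+", gene_id))
    for m in rev.finditer(region):
        p = a + m.start()  # leftmost coordinate of the PAM window
        if spec["pam_side"] == "3prime":
            s0, s1 = p + pl, p + pl + sp  # minus-strand Cas9: spacer right of PAM
        else:
            s0, s1 = p - sp, p  # minus-strand Cas12a: spacer left of PAM
        if s0 < a or s1 > b:
            continue
        spacer = reverse_complement(seq[s0:s1])
        pam = reverse_complement(seq[p:p + pl])
        if "N" in spacer or "N" in pam:
            continue
        out.append(GuideRecord("", spacer, pam, chrom, s0, "-", gene_id))
    return out


def enumerate_candidates(genome: Genome, gene: GeneModel,
                         nuclease: str = "cas12a",
                         pam_pattern: str | None = None) -> list[GuideRecord]:
    """All valid guide candidates inside a gene's CDS, de-duplicated by locus."""
    pam_pattern = pam_pattern or DEFAULT_PAMS[nuclease]
    seen, out = set(), []
    for (a, b) in gene.intervals:
        for g in _candidates_in_interval(genome, gene.chrom, a, b,
                                         nuclease, pam_pattern, gene.gene_id):
            key = (g.chrom, g.start, g.strand)
            if key not in seen:
                seen.add(key)
                out.append(g)
    for i, g in enumerate(out):
        g.guide_id = f"{gene.gene_id}_g{i}"
    return out


@dataclass
class UniquenessIndex:
    """Multiset of PAM-proximal spacer prefixes over all genome-wide candidates."""

    p: int
    counts: Counter = field(default_factory=Counter)
    prefix_end: str = "pam_proximal"

    def multiplicity(self, prefix: str) -> int:
        return self.counts[prefix]


def seed_prefix(spacer: str, p: int, nuclease: str,
                prefix_end: str = "pam_proximal") -> str:
    """The p-nt seed used for uniqueness.  PAM-proximal means the 5' end of a
    Cas12a spacer (PAM precedes it) and the 3' end of a Cas9 spacer."""
    if p > len(spacer):
        raise ValueError(f"prefix length {p} exceeds spacer length {len(spacer)}")
    if prefix_end == "5prime":
        return spacer[:p]
    if prefix_end == "3prime":
        return spacer[-p:]
    # pam_proximal (default)
    return spacer[:p] if NUCLEASES[nuclease]["pam_side"] == "5prime" else spacer[-p:]


def build_uniqueness_index(genome: Genome, nuclease: str = "cas12a", p: int = 14,
                           pam_pattern: str | None = None,
                           prefix_end: str = "pam_proximal") -> UniquenessIndex:
    """Index every genome-wide candidate (both strands, relaxed PAM: TTTN for
    Cas12a, NGG for Cas9) by its p-nt seed."""
    pam_pattern = pam_pattern or INDEX_PAMS[nuclease]
    idx = UniquenessIndex(p=p, prefix_end=prefix_end)
    for chrom in genome.chromosomes:
        for g in _candidates_in_interval(genome, chrom, 0, genome.length(chrom),
                                         nuclease, pam_pattern, ""):
            idx.counts[seed_prefix(g.spacer, p, nuclease, prefix_end)] += 1
    return idx


def uniqueness_filter(candidates: list[GuideRecord], index: UniquenessIndex,
                      nuclease: str = "cas12a") -> list[GuideRecord]:
    """Keep guides whose seed occurs exactly once genome-wide."""
    out = []
    for g in candidates:
        pre = seed_prefix(g.spacer, index.p, nuclease, index.prefix_end)
        if index.multiplicity(pre) == 1:
            out.append(g)
    return out


@dataclass
class Library:
    guides: list[GuideRecord]
    under_covered: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.guides)

    def __len__(self):
        return len(self.guides)

    @property
    def guide_ids(self):
        return [g.guide_id for g in self.guides]

    def to_dataframe(self, genome: Genome | None = None,
                     nuclease: str | None = None) -> pd.DataFrame:
        rows = []
        for g in self.guides:
            row = dict(guide_id=g.guide_id, gene=g.gene_id,
                       chrom=g.chrom if g.targeting else ".",
                       start=g.start, strand=g.strand, spacer=g.spacer,
                       pam=g.pam)
            if genome is not None and nuclease is not None and g.targeting:
                row["context"] = context_window(genome, g, nuclease)
            rows.append(row)
        return pd.DataFrame(rows)


def _cds_relative_key(g: GuideRecord, gene: GeneModel) -> int:
    """Position of the guide's 5'-most base along the gene's reading direction."""
    if gene.strand == "+":
        return g.start
    return -(g.start + len(g.spacer))


def select_guides_for_gene(candidates: list[GuideRecord], gene: GeneModel,
                           n: int) -> list[GuideRecord]:
    """Pick up to n guides walking 5'->3' along the CDS, alternating strands
    when both still have candidates (even strand representation)."""
    pools = {"+": sorted((g for g in candidates if g.strand == "+"),
                         key=lambda g: _cds_relative_key(g, gene)),
             "-": sorted((g for g in candidates if g.strand == "-"),
                         key=lambda g: _cds_relative_key(g, gene))}
    if not candidates:
        return []
    first = min(candidates, key=lambda g: _cds_relative_key(g, gene)).strand
    picked, want = [], first
    while len(picked) < n and (pools["+"] or pools["-"]):
        if not pools[want]:
            want = "-" if want == "+" else "+"
        picked.append(pools[want].pop(0))
        want = "-" if want == "+" else "+"
    return picked


def select_library(candidates_by_gene: dict[str, list[GuideRecord]],
                   genes: dict[str, GeneModel], n_per_gene: int = 8) -> Library:
    guides, under = [], {}
    for gid, cands in candidates_by_gene.items():
        sel = select_guides_for_gene(cands, genes[gid], n_per_gene)
        if len(sel) < n_per_gene:
            under[gid] = len(sel)
        guides.extend(sel)
    return Library(guides, under)


def design_library(genome: Genome, genes: list[GeneModel],
                   nuclease: str = "cas12a", n_per_gene: int = 8,
                   p: int = 14) -> Library:
    """End-to-end design: enumerate -> uniqueness-filter -> select."""
    index = build_uniqueness_index(genome, nuclease, p=p)
    gene_map = {g.gene_id: g for g in genes}
    by_gene = {}
    for gene in genes:
        cands = enumerate_candidates(genome, gene, nuclease)
        by_gene[gene.gene_id] = uniqueness_filter(cands, index, nuclease)
    return select_library(by_gene, gene_map, n_per_gene)


def design_nontargeting(genome: Genome, count: int, spacer_len: int = 25,
                        p: int = 10, seed: int = 0,
                        max_attempts_per_guide: int = 1000) -> list[GuideRecord]:
    """Random spacers whose first ``p`` nt occur nowhere in the genome, on
    either strand; used to anchor the inactive-guide score distribution."""
    rng = np.random.default_rng(seed)
    haystack = "N".join(genome[c] for c in genome.chromosomes)
    haystack = haystack + "N" + reverse_complement(haystack)
    out, attempts = [], 0
    limit = max(count, 1) * max_attempts_per_guide
    while len(out) < count:
        if attempts >= limit:
            raise RuntimeError(
                f"could not design {count} non-targeting guides after "
                f"{attempts} attempts (genome too small or p too short)")
        attempts += 1
        spacer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, spacer_len)])
        if spacer[:p] in haystack:
            continue
        out.append(GuideRecord(f"nt_{len(out)}", spacer, "", None, -1, ".",
                               "non-targeting"))
    return out


def write_library_tsv(library: Library, path, genome: Genome | None = None,
                      nuclease: str | None = None) -> None:
    library.to_dataframe(genome, nuclease).to_csv(path, sep="\t", index=False)


def read_library_tsv(path) -> Library:
    df = pd.read_csv(path, sep="\t")
    guides = []
    for _, r in df.iterrows():
        chrom = None if r["chrom"] == "." else r["chrom"]
        guides.append(GuideRecord(r["guide_id"], r["spacer"],
                                  "" if pd.isna(r["pam"]) else r["pam"],
                                  chrom, int(r["start"]), r["strand"],
                                  str(r["gene"])))
    return Library(guides)


def write_spacer_fasta(library: Library, path) -> None:
    with open(path, "w") as fh:
        for g in library:
            fh.write(f">{g.guide_id}\n{g.spacer}\n")
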