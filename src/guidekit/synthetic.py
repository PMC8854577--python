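"""Synthetic fixtures: genomes with PAM-seeded genes, occupancy tracks,
ground-truth activity functions, and screens whose read counts encode a known
cutting score.

Everything is deterministic given a seed.  The screen sampler inverts the CS
definition: control abundances are Dirichlet, treatment abundances are the
control abundances scaled by 2^(−CS) and renormalized (the renormalization
constant is folded back into the reported true CS so that the expected
log2 control/treatment abundance ratio equals the stored truth exactly), and
counts are multinomial at the requested depth.  This is the simplest sampling
model consistent with relative-abundance screens, and it makes recovery-error
tolerances derivable from depth alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, GeneModel, context_window, BASES
from .design import GuideRecord, Library, find_pam_sites, design_nontargeting
from .genome import NUCLEASES
from .occupancy import OccupancyTrack
from .screen import ReadCountTable

_V = "ACG"  # the V in TTTV


def make_genome(n_chrom: int = 2, lengths=50_000, gc: float = 0.49,
                genes_per_chrom: int = 50, gene_length: int = 900,
                pam_interval: int = 70, seed: int = 0
                ) -> tuple[Genome, list[GeneModel]]:
    """Random multi-chromosome genome with CDS annotations and guaranteed
    Cas12a PAM density.

    TTTV motifs are planted every ``pam_interval`` bp inside each CDS,
    alternating strands, so every gene carries a predictable minimum number
    of candidate sites.  GC content applies to the random background.
    """
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    core = NUCLEASES["cas12a"]["spacer_len"] + NUCLEASES["cas12a"]["pam_len"]
    if pam_interval < core + 5:
        raise ValueError(f"pam_interval {pam_interval} too dense for a "
                         f"{core} bp spacer+PAM footprint")
    if gene_length < pam_interval + core:
        raise ValueError("gene_length too short for the requested PAM rate")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences, genes = {}, []
    for ci in range(n_chrom):
        L = lengths[ci]
        arr = rng.choice(list(BASES), size=L, p=p)
        name = f"chr{ci + 1}"
        # evenly spaced non-overlapping genes with flanking spacing
        slot = L // genes_per_chrom
        if slot < gene_length + 100:
            raise ValueError("chromosome too short for requested genes")
        for gi in range(genes_per_chrom):
            a = gi * slot + 50
            b = a + gene_length
            gid = f"{name}_gene{gi + 1}"
            strand = "+" if (gi % 2 == 0) else "-"
            genes.append(GeneModel(gid, name, [(a, b)], strand))
            # plant TTTV PAMs, alternating strands, spacer fully inside CDS
            k = 0
            for pos in range(a + 30, b - core, pam_interval):
                if k % 2 == 0:  # plus strand: TTTV then 25 bp spacer
                    arr[pos:pos + 3] = list("TTT")
                    arr[pos + 3] = rng.choice(list(_V))
                else:  # minus strand: plant revcomp(TTTV) = BAAA
                    comp = {"A": "T", "C": "G", "G": "C"}[rng.choice(list(_V))]
                    arr[pos] = comp
                    arr[pos + 1:pos + 4] = list("AAA")
                k += 1
        sequences[name] = "".join(arr)
    return Genome(sequences, source=f"synthetic(seed={seed})"), genes


def make_occupancy_track(genome: Genome, smooth_bp: int = 150,
                         amplitude: float = 10.0, seed: int = 0
                         ) -> OccupancyTrack:
    """Smooth non-negative coverage: Gaussian-filtered white noise squashed
    through a logistic, scaled by ``amplitude`` (nucleosome-scale smoothness)."""
    rng = np.random.default_rng(seed)
    values = {}
    half = 3 * smooth_bp
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / smooth_bp) ** 2)
    kernel /= kernel.sum()
    for chrom in genome.chromosomes:
        L = genome.length(chrom)
        z = np.convolve(rng.normal(size=L + 2 * half), kernel, mode="same")
        z = z[half:half + L]
        z /= max(z.std(), 1e-12)
        values[chrom] = amplitude / (1.0 + np.exp(-2.0 * z))
    return OccupancyTrack(values)


@dataclass
class ActivityFunction:
    """Ground-truth sequence–activity map: per-position per-base weights over
    the context window, a (non-positive) occupancy coefficient, and Gaussian
    label noise.  true CS = Σ weights[base, pos] + β·occupancy + N(0, σ)."""

    weights: np.ndarray  # (4, window length)
    beta: float = 0.0
    sigma: float = 0.3
    intercept: float = 1.5

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != 4:
            raise ValueError("weights must be (4, window_length)")
        if self.beta > 0:
            raise ValueError("occupancy coefficient must be <= 0 "
                             "(occupancy impedes cutting)")

    @property
    def window_length(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def random(cls, length: int, scale: float = 0.35, beta: float = 0.0,
               sigma: float = 0.3, active: slice | None = None,
               intercept: float = 1.5, seed: int = 0) -> "ActivityFunction":
        """Random map with effects confined to ``active`` positions (default:
        the whole window); per-position weights are mean-centered."""
        rng = np.random.default_rng(seed)
        w = np.zeros((4, length))
        sl = active if active is not None else slice(0, length)
        w[:, sl] = rng.normal(0, scale, size=w[:, sl].shape)
        w -= w.mean(axis=0, keepdims=True)
        return cls(w, beta=beta, sigma=sigma, intercept=intercept)

    def sequence_effect(self, windows) -> np.ndarray:
        idx = {b: i for i, b in enumerate(BASES)}
        out = np.empty(len(windows))
        for j, w in enumerate(windows):
            if len(w) != self.window_length:
                raise ValueError(f"window length {len(w)} != "
                                 f"{self.window_length}")
            out[j] = sum(self.weights[idx[b], p] for p, b in enumerate(w))
        return out + self.intercept

    def true_cs(self, windows, occupancy=None, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        cs = self.sequence_effect(windows)
        if self.beta != 0.0:
            if occupancy is None:
                raise ValueError("beta != 0 requires occupancy values")
            cs = cs + self.beta * np.asarray(occupancy, dtype=float).ravel()
        if self.sigma > 0:
            cs = cs + rng.normal(0, self.sigma, size=len(cs))
        return cs


@dataclass
class SyntheticScreen:
    table: ReadCountTable
    true_cs: pd.Series
    depth: int
    replicates: int
    seed: int


def make_screen(guides, true_cs, depth: int = 1_000_000, replicates: int = 3,
                dirichlet_alpha: float = 10.0, nontargeting_cs: float = -1.5,
                seed: int = 0) -> SyntheticScreen:
    """Screen read counts whose log-ratios encode a known CS.

    ``guides`` is a Library or list of GuideRecord; non-targeting guides get
    the fixed control-population offset ``nontargeting_cs``.  Expected
    log2(control/treatment abundance) equals the *returned* true CS exactly
    (the treatment renormalization constant is absorbed into the truth).
    """
    if depth < 10_000:
        raise ValueError("depth must be >= 1e4 for a meaningful screen")
    guides = list(guides)
    ids = [g.guide_id for g in guides]
    is_nt = np.array([g.gene_id == "non-targeting" for g in guides])
    true_vals = np.asarray(true_cs, dtype=float).ravel()
    cs = np.empty(len(guides))
    if len(true_vals) == len(guides):
        cs[:] = true_vals
    elif len(true_vals) == int((~is_nt).sum()):
        cs[~is_nt] = true_vals
    else:
        raise ValueError(f"true_cs length {len(true_vals)} matches neither all "
                         f"guides ({len(guides)}) nor targeting guides "
                         f"({int((~is_nt).sum())})")
    cs[is_nt] = nontargeting_cs
    if np.any(np.abs(cs) > 20):
        warnings.warn("extreme CS values clipped to ±20 to avoid underflow")
        cs = np.clip(cs, -20, 20)
    rng = np.random.default_rng(seed)
    p_ctrl = rng.dirichlet(np.full(len(guides), dirichlet_alpha))
    q = p_ctrl * np.exp2(-cs)
    Z = q.sum()
    q /= Z
    cs = cs + np.log2(Z)  # fold normalization into the reported truth
    cols, conds, reps = {}, [], []
    for r in range(1, replicates + 1):
        cols[f"control_r{r}"] = rng.multinomial(depth, p_ctrl)
        conds.append("control"); reps.append(r)
    for r in range(1, replicates + 1):
        cols[f"treatment_r{r}"] = rng.multinomial(depth, q)
        conds.append("treatment"); reps.append(r)
    counts = pd.DataFrame(cols, index=ids)
    samples = pd.DataFrame({"condition": conds, "replicate": reps},
                           index=list(cols))
    table = ReadCountTable(counts, samples)
    return SyntheticScreen(table, pd.Series(cs, index=ids, name="true_cs"),
                           int(depth), replicates, seed)


def sample_pam_guides(genome: Genome, n: int | None = None,
                      nuclease: str = "cas12a", pam_pattern: str = "TTTN",
                      seed: int = 0) -> list[GuideRecord]:
    """Guide records at genome-wide PAM sites (both strands), in-bounds for
    context extraction; subsampled to ``n`` if requested."""
    spec = NUCLEASES[nuclease]
    sp, pl = spec["spacer_len"], spec["pam_len"]
    ctx = spec["context_len"]
    out = []
    for chrom, pos, strand in find_pam_sites(genome, pam_pattern, True):
        if spec["pam_side"] == "5prime":
            start = pos + pl if strand == "+" else pos - sp
        else:
            start = pos - sp if strand == "+" else pos + pl
        g = GuideRecord(f"g_{chrom}_{pos}_{strand}", "A" * sp, "", chrom,
                        max(start, 0), strand, "genomewide")
        if start < 0:
            continue
        try:
            window = context_window(genome, g, nuclease, ctx)
        except Exception:
            continue
        seq = genome[chrom]
        spacer = seq[start:start + sp]
        if strand == "-":
            from .genome import reverse_complement
            spacer = reverse_complement(spacer)
        if "N" in spacer:
            continue
        g.spacer = spacer
        out.append(g)
    if n is not None and n < len(out):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(out), size=n, replace=False)
        out = [out[i] for i in sorted(keep)]
    return out


def make_training_set(genome: Genome, library, activity: ActivityFunction,
                      occupancy: pd.Series | None = None,
                      nuclease: str = "cas12a", seed: int = 0) -> pd.DataFrame:
    """Labeled table (guide_id, context, occupancy, cs) for supervised
    training; labels come from the ground-truth activity function."""
    guides = [g for g in library if g.targeting]
    windows = [context_window(genome, g, nuclease, activity.window_length)
               for g in guides]
    ids = [g.guide_id for g in guides]
    occ = (occupancy.reindex(ids).to_numpy() if occupancy is not None
           else np.zeros(len(ids)))
    cs = activity.true_cs(windows, occ, seed=seed)
    return pd.DataFrame({"guide_id": ids, "context": windows,
                         "occupancy": occ, "cs": cs})
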