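"""Run configuration and the end-to-end workflow.

A single :class:`RunConfig` (YAML-serializable) drives the stages
simulate -> score -> [pretrain] -> train -> evaluate; every output directory
gets a manifest recording the config hash, per-stage seeds and output-file
checksums, so re-running the same config reproduces the same manifest.
The global seed is fanned out per stage deterministically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import read_fasta, write_fasta, write_gff3, read_gff3, extract_kmers
from .design import (design_library, design_nontargeting, Library,
                     write_library_tsv, read_library_tsv)
from .screen import (read_counts_tsv, cutting_scores_from_table, write_cs_tsv,
                     write_counts_tsv, control_summary)
from .occupancy import read_bedgraph, write_bedgraph, occupancy_for_library
from .model import (ModelSpec, TrainConfig, pretrain_cae, train_predictor,
                    save_model, ACTIVE_CS_THRESHOLDS)
from .evaluation import correlations, binarize_and_roc
from .synthetic import (make_genome, make_occupancy_track, ActivityFunction,
                        make_screen, make_training_set)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Validated inputs for the pipeline; serialized alongside outputs."""

    nuclease: str = "cas12a"
    seed: int = 0
    outdir: str = "gdk_run"
    # synthetic preset (used when no genome path is given)
    n_chrom: int = 2
    chrom_length: int = 20_000
    genes_per_chrom: int = 20
    n_per_gene: int = 8
    n_controls: int = 30
    depth: int = 200_000
    replicates: int = 3
    activity_beta: float = 0.0
    activity_sigma: float = 0.3
    # training budget
    epochs: int = 30
    patience: int = 10
    cae_epochs: int = 5
    pretrain: bool = True
    variant: str = "fc8+fc9"
    use_occupancy: bool = False
    cs_threshold: float | None = None

    def __post_init__(self):
        if self.nuclease not in ("cas9", "cas12a"):
            raise ValueError(f"unknown nuclease {self.nuclease!r}")
        if self.seed < 0 or self.seed >= 2 ** 31:
            raise ValueError("seed must be in [0, 2^31)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> score -> pretrain -> train -> evaluate; returns the
    artifact directory (with manifest.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    outputs: dict[str, str] = {}
    n_ctx = 28 if config.nuclease == "cas9" else 32

    # --- simulate ----------------------------------------------------------
    s_seed = stage_seed(config.seed, "simulate")
    genome, genes = make_genome(config.n_chrom, config.chrom_length,
                                genes_per_chrom=config.genes_per_chrom,
                                seed=s_seed)
    write_fasta(genome, out / "genome.fa")
    write_gff3(genes, out / "genes.gff3")
    track = make_occupancy_track(genome, seed=s_seed + 1)
    write_bedgraph(track, out / "occupancy.bedgraph")
    library = design_library(genome, genes, config.nuclease,
                             n_per_gene=config.n_per_gene)
    library.guides.extend(design_nontargeting(
        genome, config.n_controls, seed=s_seed + 2))
    write_library_tsv(library, out / "library.tsv")
    occ = occupancy_for_library(track, library, config.nuclease)
    activity = ActivityFunction.random(n_ctx, beta=config.activity_beta,
                                       sigma=config.activity_sigma,
                                       seed=s_seed + 3)
    labels = make_training_set(genome, library, activity,
                               occupancy=occ, nuclease=config.nuclease,
                               seed=s_seed + 4)
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    screen = make_screen(library, labels.set_index("guide_id")["cs"]
                         .reindex([g.guide_id for g in library
                                   if g.targeting]).to_numpy(),
                         depth=config.depth, replicates=config.replicates,
                         seed=s_seed + 5)
    write_counts_tsv(screen.table, out / "counts.tsv")
    screen.table.samples.rename_axis("sample").to_csv(out / "samples.tsv", sep="\t")

    # --- score -------------------------------------------------------------
    cs = cutting_scores_from_table(screen.table)
    write_cs_tsv(cs, out / "cs.tsv")
    nt_ids = [g.guide_id for g in library if not g.targeting]
    ctrl = control_summary(cs, nt_ids) if len(nt_ids) >= 2 else None

    # --- pretrain + train --------------------------------------------------
    spec = ModelSpec(nuclease=config.nuclease, n=n_ctx, variant=config.variant,
                     use_occupancy=config.use_occupancy)
    tc = TrainConfig(epochs=config.epochs, patience=config.patience,
                     cae_epochs=config.cae_epochs,
                     seed=stage_seed(config.seed, "train"))
    enc_weights = None
    if config.pretrain:
        rng = np.random.default_rng(stage_seed(config.seed, "pretrain"))
        kmers = [k for k in extract_kmers(genome, n_ctx, step=97)]
        kmers = [kmers[i] for i in
                 rng.choice(len(kmers), min(2000, len(kmers)), replace=False)]
        enc_weights = pretrain_cae(kmers, spec, tc)
    # train on the screen-estimated CS (the realistic path), using the
    # guide's measured context and occupancy
    targeting = labels["guide_id"].tolist()
    dataset = (labels["context"].tolist(), labels["occupancy"].to_numpy(),
               cs.loc[targeting, "cs"].to_numpy())
    trained = train_predictor(spec, dataset, tc, encoder_weights=enc_weights)
    save_model(trained.estimator, str(out / "model"))

    # --- evaluate ----------------------------------------------------------
    r_p, r_s = correlations(trained.test_predictions, trained.test_targets)
    report = {"n_test": int(len(trained.test_targets)),
              "pearson": r_p, "spearman": r_s,
              "control_summary": ({"mean": ctrl["mean"], "sd": ctrl["sd"],
                                   "n": ctrl["n"]} if ctrl else None)}
    threshold = (config.cs_threshold if config.cs_threshold is not None
                 else ACTIVE_CS_THRESHOLDS[config.nuclease])
    try:
        roc = binarize_and_roc(trained.test_predictions, trained.test_targets,
                               threshold)
        report["auroc"] = roc.auroc
        roc.write_roc_tsv(out / "roc.tsv")
    except ValueError as e:
        report["auroc"] = None
        report["auroc_note"] = str(e)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    # --- manifest ----------------------------------------------------------
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            outputs[f.name] = _sha256(f)
    manifest = {"guidekit_version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "stage_seeds": {s: stage_seed(config.seed, s)
                                for s in ("simulate", "pretrain", "train")},
                "outputs": outputs}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
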