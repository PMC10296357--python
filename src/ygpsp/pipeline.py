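"""End-to-end orchestration of the screen analysis.

A single config drives design/simulate -> count -> psi -> train ->
predict -> features, writing every stage's output plus a manifest JSON
(parameters, package version, output checksums) into a run directory.
Reruns with ``resume=True`` skip stages whose outputs already exist with
the checksums recorded in the manifest, so deleting one intermediate
regenerates only it and its downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counting import BinCountTable, TrimSpec, build_index, count_bins, normalize_bins, write_match_stats
from .library import DEFAULT_FLANK3, DEFAULT_FLANK5, tiles_to_manifest, manifest_to_tiles
from .model import build_training_set, call_degrons, DegronClassifier, save_model, scan_protein
from .psi import psi_table, residues_from_tiles, write_profiles_tsv
from .simulate import SimConfig, simulate_screen, write_fastq
from .structure import hydropathy_vs_probability

log = logging.getLogger(__name__)

# Stage defaults, each traceable to the protocol's printed value.
CONSTANTS = {
    "tile_nt": 51,            # fragment length (nt)
    "overlap_nt": 36,         # overlap between neighbouring fragments
    "tile_aa": 17,            # peptide length
    "norm_total": 1_000_000,  # reads/bin after normalisation
    "max_mismatch": 1,        # substitutions allowed in matching
    "min_reads": 50,          # combined-read filter for training
    "psi_lo": 2.2,            # below: unstable (label 1)
    "psi_hi": 2.8,            # above: stable (label 0)
    "ridge_lambda": 0.001,    # L2 strength
    "median_window": 5,       # running-median window (residues)
    "degron_cutoff": 0.85,    # probability cutoff for degron calls
    "probe_radius": 1.4,      # ASA probe radius (A)
}


@dataclass
class PipelineConfig:
    """All stage parameters plus paths and logging for one run."""

    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    # design / simulate
    sim: SimConfig = field(default_factory=SimConfig)
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    # counting
    max_mismatch: int = CONSTANTS["max_mismatch"]
    norm_total: int = CONSTANTS["norm_total"]
    # psi
    track: str = "coverage-mean"
    median_window: int = CONSTANTS["median_window"]
    # training
    min_reads: int = CONSTANTS["min_reads"]
    psi_lo: float = CONSTANTS["psi_lo"]
    psi_hi: float = CONSTANTS["psi_hi"]
    ridge_lambda: float = CONSTANTS["ridge_lambda"]
    feature_mode: str = "counts"
    # prediction / features
    degron_cutoff: float = CONSTANTS["degron_cutoff"]
    write_fastq: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["protein_length_range"] = list(self.sim.protein_length_range)
        d["sim"]["bin_boundaries"] = list(self.sim.bin_boundaries)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        for key in ("protein_length_range", "bin_boundaries"):
            if key in sim:
                sim[key] = tuple(sim[key])
        return cls(sim=SimConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.record = {"stage": stage, "error": type(cause).__name__, "message": str(cause)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute all stages on a synthetic screen; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest_path = out / "manifest.json"
    old_checks: dict[str, str] = {}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            old_checks = json.load(fh).get("checksums", {})

    outputs: dict[str, Path] = {
        "library": out / "library.tsv",
        "truth": out / "truth.tsv",
        "counts": out / "counts.tsv",
        "match_stats": out / "match_stats.json",
        "psi": out / "psi.tsv",
        "profiles": out / "profiles.tsv",
        "model": out / "model.json",
        "scan": out / "scan.tsv",
        "calls": out / "calls.tsv",
        "features": out / "features.json",
    }
    stages_run: list[str] = []

    def fresh(*names: str) -> bool:
        """True when every named output exists with its recorded checksum.

        Once any stage has rerun, everything downstream reruns too.
        """
        if not resume or stages_run:
            return False
        for n in names:
            p = outputs[n]
            if not p.exists() or old_checks.get(p.name) != _sha256(p):
                return False
        return True

    cfg = dataclasses.replace(config.sim, seed=config.seed)

    # -- simulate (includes library design on the synthetic proteome) ------
    try:
        if fresh("library", "truth", "counts", "match_stats"):
            log.info("resume: simulate/count outputs up to date")
            manifest_df = pd.read_csv(outputs["library"], sep="\t")
            counts = BinCountTable.read_tsv(outputs["counts"])
        else:
            stages_run.append("simulate")
            proteins, tiles, sim_counts, truth, reads = simulate_screen(
                cfg, with_reads=True
            )
            manifest_df = tiles_to_manifest(tiles)
            manifest_df.to_csv(outputs["library"], sep="\t", index=False)
            truth.write_tsv(outputs["truth"])
            if config.write_fastq:
                for g, rr in reads.items():
                    write_fastq(rr, out / f"gate{g}.fastq", g)
            # -- count ------------------------------------------------------
            stages_run.append("count")
            index = build_index(tiles)
            trim = TrimSpec(mode="anchor", anchor=config.flank5)
            counts, stats = count_bins(reads, index, trim)
            counts = normalize_bins(counts, total=config.norm_total)
            counts.write_tsv(outputs["counts"])
            write_match_stats(stats, outputs["match_stats"])
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate/count", e) from e

    # -- psi ----------------------------------------------------------------
    try:
        if fresh("psi", "profiles"):
            log.info("resume: psi outputs up to date")
            psis = pd.read_csv(outputs["psi"], sep="\t")
        else:
            stages_run.append("psi")
            if counts.normalized is None:
                counts = normalize_bins(counts, total=config.norm_total)
            psis = psi_table(counts)
            psis.to_csv(outputs["psi"], sep="\t", index=False)
            profiles = residues_from_tiles(
                psis, manifest_df, track=config.track, window=config.median_window
            )
            write_profiles_tsv(profiles, outputs["profiles"])
    except Exception as e:  # noqa: BLE001
        raise StageError("psi", e) from e

    # -- train ---------------------------------------------------------------
    try:
        if fresh("model"):
            log.info("resume: model up to date")
            from .model import load_model

            clf = load_model(outputs["model"])
        else:
            stages_run.append("train")
            pep_by_id = dict(zip(manifest_df["peptide_id"], manifest_df["peptide"]))
            ts = build_training_set(
                psis, pep_by_id,
                min_reads=config.min_reads, lo=config.psi_lo, hi=config.psi_hi,
            )
            clf = DegronClassifier(
                ridge_lambda=config.ridge_lambda, feature_mode=config.feature_mode
            ).fit(ts.peptides, ts.labels)
            save_model(
                clf, outputs["model"],
                metadata={
                    "n_train": len(ts.peptides),
                    "class_balance": ts.class_balance,
                    "excluded": {
                        "low_reads": ts.n_low_reads,
                        "midrange": ts.n_midrange,
                        "boundary": ts.n_boundary,
                    },
                },
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("train", e) from e

    # -- predict + features ---------------------------------------------------
    try:
        if fresh("scan", "calls", "features"):
            log.info("resume: prediction outputs up to date")
        else:
            stages_run.append("predict")
            scan_rows, call_rows = [], []
            proteins_aa = (
                manifest_df.sort_values(["protein_id", "tile_index"])
                .groupby("protein_id", sort=True)
            )
            for pid, grp in proteins_aa:
                # reconstruct the protein from its tiles (5-residue steps)
                seq_parts = [grp.iloc[0]["peptide"]]
                prev_end = int(grp.iloc[0]["aa_start"]) + len(grp.iloc[0]["peptide"])
                for r in grp.iloc[1:].itertuples(index=False):
                    start = int(r.aa_start)
                    if start + len(r.peptide) > prev_end:
                        seq_parts.append(r.peptide[prev_end - start:])
                        prev_end = start + len(r.peptide)
                seq = "".join(seq_parts)
                prof = scan_protein(clf, seq)
                prof.protein_id = pid
                scan_rows.append(prof.to_frame())
                for c in call_degrons(prof, cutoff=config.degron_cutoff):
                    call_rows.append(
                        {"protein_id": pid, "start0": c.start - 1, "end": c.end,
                         "peak_probability": c.peak_probability}
                    )
            pd.concat(scan_rows).to_csv(outputs["scan"], sep="\t", index=False)
            pd.DataFrame(
                call_rows, columns=["protein_id", "start0", "end", "peak_probability"]
            ).to_csv(outputs["calls"], sep="\t", index=False)

            stages_run.append("features")
            _, rho, pval = hydropathy_vs_probability(
                list(manifest_df["peptide"]), clf
            )
            with open(outputs["features"], "w") as fh:
                json.dump(
                    {"kd_spearman_rho": rho, "kd_spearman_p": pval,
                     "n_peptides": int(len(manifest_df)),
                     "n_degron_calls": len(call_rows)},
                    fh, indent=2,
                )
    except Exception as e:  # noqa: BLE001
        raise StageError("predict/features", e) from e

    checksums = {p.name: _sha256(p) for p in outputs.values() if p.exists()}
    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": config.to_dict(),
                "stages_run": stages_run,
                "checksums": checksums,
            },
            fh, indent=2,
        )
    return out
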