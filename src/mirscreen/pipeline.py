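"""End-to-end orchestration: pooled screen (count -> scale -> enrich ->
score) and arrayed screen (B-scores -> replicate agreement -> z-scores),
with a YAML config, one master seed, and a JSON run manifest.

Every run writes a manifest recording the tool version, a hash of the
configuration, the master seed, per-fraction read totals and the result
of the count-conservation check, so a run can be audited and reproduced
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .deconvolution import ReadCountTable, count_reads
from .library import load_construct_library
from .plates import PlateGrid, b_score, plate_z_scores, rc_to_well, replicate_agreement
from .scoring import HitTable, score_counts

__all__ = ["RunConfig", "PipelineError", "run_pooled_pipeline", "run_arrayed_pipeline"]

log = logging.getLogger("mirscreen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (flags > file > defaults)."""

    # pooled-screen inputs (either counts_tsv, or both fastq paths + library)
    library_path: str | None = None
    library_format: str = "tsv"
    counts_tsv: str | None = None
    fastq_control: str | None = None
    fastq_invasive: str | None = None
    # arrayed-screen inputs
    plate_csvs: list[str] = field(default_factory=list)
    roles_csvs: list[str] = field(default_factory=list)
    # outputs
    out_dir: str = "."
    # scoring parameters
    pseudocount: float = 0.5
    threshold: float = 1.0
    # deconvolution tolerances
    max_anchor_mismatch: int = 2
    max_hamming: int = 5
    min_fragment: int = 20
    # run control
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        paths = [
            p
            for p in [self.library_path, self.counts_tsv, self.fastq_control,
                      self.fastq_invasive, *self.plate_csvs, *self.roles_csvs]
            if p
        ]
        if len(set(paths)) != len(paths):
            raise ValueError("config references the same path more than once")


def _write_manifest(path: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "tool": "mirscreen",
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        **extra,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _cleanup(outputs: list[Path]) -> None:
    for p in outputs:
        try:
            p.unlink(missing_ok=True)
        except OSError:
            pass


def run_pooled_pipeline(config: RunConfig) -> tuple[HitTable, dict]:
    """Run counting (or count-table ingestion) and E x R scoring; write the
    hit table and manifest under ``config.out_dir``."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hits_path = out_dir / "hits.tsv"
    counts_path = out_dir / "counts.tsv"
    manifest_path = out_dir / "manifest.json"
    written: list[Path] = []
    try:
        stage = "count"
        if config.counts_tsv:
            log.info("reading precomputed counts from %s", config.counts_tsv)
            counts = ReadCountTable.from_tsv(config.counts_tsv)
        else:
            if not (config.library_path and config.fastq_control and config.fastq_invasive):
                raise ValueError(
                    "need either counts_tsv or library_path + both FASTQ paths"
                )
            library = load_construct_library(
                config.library_path, format=config.library_format
            )
            log.info("counting reads against %d constructs", len(library))
            counts = count_reads(
                config.fastq_control,
                config.fastq_invasive,
                library,
                max_anchor_mismatch=config.max_anchor_mismatch,
                max_hamming=config.max_hamming,
                min_fragment=config.min_fragment,
            )
            counts.to_tsv(counts_path)
            written += [counts_path, Path(str(counts_path) + ".summary.json")]
        counts.validate()

        stage = "score"
        log.info("scoring with pseudocount=%g threshold=%g",
                 config.pseudocount, config.threshold)
        hits = score_counts(
            counts, pseudocount=config.pseudocount, threshold=config.threshold
        )
        hits.to_tsv(hits_path)
        written.append(hits_path)

        stage = "manifest"
        extra = {
            "pipeline": "pooled",
            "parameters": {
                "pseudocount": config.pseudocount,
                "threshold": config.threshold,
                "max_anchor_mismatch": config.max_anchor_mismatch,
                "max_hamming": config.max_hamming,
            },
            "total_reads": counts.total_reads,
            "unassigned": counts.unassigned,
            "ambiguous": counts.ambiguous,
            "conservation_ok": True,  # counts.validate() above would have raised
            "n_constructs": int(len(counts.counts)),
            "n_hits": hits.n_called,
        }
        _write_manifest(manifest_path, config, extra)
        return hits, extra
    except Exception as exc:
        _cleanup(written + [manifest_path])
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def run_arrayed_pipeline(config: RunConfig) -> dict:
    """B-score two replicate plates, report their agreement and per-well
    z-scores against control wells; write TSVs and a manifest."""
    config.validate_paths()
    if len(config.plate_csvs) != 2:
        raise PipelineError("load", "exactly two replicate plate CSVs are required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest_path = out_dir / "manifest.json"
    try:
        stage = "load"
        roles = list(config.roles_csvs) or [None, None]
        if len(roles) != 2:
            raise ValueError("need zero or two roles CSVs")
        plates = [
            PlateGrid.from_csv(p, r) for p, r in zip(config.plate_csvs, roles)
        ]
        if plates[0].shape != plates[1].shape:
            raise ValueError(
                f"replicate plates differ in shape: {plates[0].shape} vs {plates[1].shape}"
            )

        stage = "bscore"
        grids = [b_score(p) for p in plates]
        agreement = replicate_agreement(grids[0], grids[1])

        stage = "zscore"
        zs = []
        for p in plates:
            has_controls = (p.roles == "control").any()
            zs.append(plate_z_scores(p) if has_controls else None)

        stage = "write"
        out_path = out_dir / "plate_scores.tsv"
        with open(out_path, "w") as fh:
            fh.write("well\trole\tb_rep1\tb_rep2\tz_rep1\tz_rep2\n")
            n_rows, n_cols = plates[0].shape
            for r in range(n_rows):
                for c in range(n_cols):
                    z1 = "" if zs[0] is None else repr(float(zs[0][r, c]))
                    z2 = "" if zs[1] is None else repr(float(zs[1][r, c]))
                    fh.write(
                        f"{rc_to_well(r, c)}\t{plates[0].roles[r, c]}\t"
                        f"{float(grids[0].b[r, c])!r}\t{float(grids[1].b[r, c])!r}\t"
                        f"{z1}\t{z2}\n"
                    )
        written.append(out_path)

        stage = "manifest"
        extra = {
            "pipeline": "arrayed",
            "agreement": agreement,
            "plate_shape": list(plates[0].shape),
            "degenerate": [g.degenerate for g in grids],
            "mad": [g.mad for g in grids],
        }
        _write_manifest(manifest_path, config, extra)
        return {"b_scores": grids, "z_scores": zs, "agreement": agreement,
                "manifest": extra}
    except Exception as exc:
        _cleanup(written + [manifest_path])
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
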