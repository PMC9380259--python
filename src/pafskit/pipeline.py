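"""Run configuration, structured logging and the end-to-end workflows.

Two workflows are orchestrated from one config: viability plates ->
Hill fits -> EC50 -> responder labels, and phosphosite table -> class-I
filter -> per-batch variance stabilization -> batch correction ->
s0-moderated differential test -> PAFS / KSEA / motif annotation.  A
fixed config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .dose_response import classify_responder, compute_ec50, fit_hill, normalize_plate
from .enrichment import ksea, motif_enrichment, pafs_rank
from .phospho_stats import (
    DifferentialConfig,
    batch_correct,
    filter_class1,
    sam_test,
    vsn_transform,
)

__all__ = ["RunConfig", "RunLog", "StageRecord", "ConfigError", "PipelineError", "run_pipeline"]


class ConfigError(ValueError):
    """Configuration failed validation before any work was done."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs were removed."""


@dataclass
class RunConfig:
    out_dir: str
    plates: str | None = None
    phospho_table: str | None = None
    functional_scores: str | None = None
    kinase_map: str | None = None
    contrast: tuple[str, str] = ("treated", "control")
    localization_threshold: float = 0.75
    s0: float = 0.1
    fdr: float = 0.05
    score_threshold: float = 0.6
    responder_cutoff_nM: float = 1000.0
    min_substrates: int = 3
    motif_alpha: float = 0.01
    filter_first: bool = True  # class-I filter before normalization
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 <= self.localization_threshold <= 1, "localization_threshold in [0, 1]"),
            (self.s0 >= 0, "s0 >= 0"),
            (0 < self.fdr < 1, "fdr in (0, 1)"),
            (0 <= self.score_threshold <= 1, "score_threshold in [0, 1]"),
            (self.responder_cutoff_nM > 0, "responder_cutoff_nM > 0"),
            (self.min_substrates >= 1, "min_substrates >= 1"),
            (0 < self.motif_alpha < 1, "motif_alpha in (0, 1)"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))
        if self.plates is None and self.phospho_table is None:
            raise ConfigError("config needs at least one of plates / phospho_table")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "contrast" in raw and isinstance(raw["contrast"], (list, str)):
            c = raw["contrast"]
            raw["contrast"] = tuple(c.split(":")) if isinstance(c, str) else tuple(c)
        return cls(**raw)


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    elapsed_s: float = 0.0


@dataclass
class RunLog:
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "stages": [asdict(s) for s in self.stages]}, indent=2
        )


class _StageRunner:
    def __init__(self, log: RunLog, outputs: list[Path]):
        self.log = log
        self.outputs = outputs

    def run(self, stage: str, fn, n_in: int, params: dict | None = None):
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                out, n_out = fn()
        except Exception as exc:
            for p in self.outputs:
                p.unlink(missing_ok=True)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        self.log.stages.append(
            StageRecord(
                stage=stage,
                n_in=n_in,
                n_out=n_out,
                params=params or {},
                warnings=[str(w.message) for w in caught],
                elapsed_s=round(time.perf_counter() - t0, 4),
            )
        )
        return out


def run_pipeline(config: RunConfig) -> RunLog:
    """Execute the configured workflows in fixed order; returns the run log.

    Outputs are written under ``config.out_dir`` with a ``# seed=...``
    header comment; any stage error aborts the run with the stage name
    after removing partial outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog(seed=config.seed)
    written: list[Path] = []
    runner = _StageRunner(log, written)
    header = f"seed={config.seed}"

    if config.plates is not None:

        def _dose_response():
            plates = pio.read_plate_csv(config.plates)
            rows = []
            for plate in plates:
                doses, resp = normalize_plate(plate)
                fit = fit_hill(doses, resp)
                ec = compute_ec50(fit) if fit.converged else None
                label = (
                    classify_responder(plate.sample_id, ec, config.responder_cutoff_nM)
                    if ec is not None
                    else None
                )
                rows.append(
                    {
                        "sample_id": plate.sample_id,
                        "drug": plate.drug,
                        "k": fit.k,
                        "m": fit.m,
                        "n": fit.n,
                        "ec50_nM": ec.serialize() if ec is not None else "NA",
                        "ec50_reason": (ec.reason or "") if ec is not None else "fit failed",
                        "responder": bool(label.responder) if label is not None else False,
                    }
                )
            path = out_dir / "ec50.tsv"
            written.append(path)
            pio._write_lines(path, pd.DataFrame(rows), "\t", header)
            return rows, len(rows)

        runner.run("dose_response", _dose_response, n_in=0)

    if config.phospho_table is not None:
        table = runner.run(
            "read_phospho",
            lambda: ((t := pio.read_phospho_tsv(config.phospho_table)), t.n_sites),
            n_in=0,
        )
        n0 = table.n_sites
        if config.filter_first:
            table = runner.run(
                "filter_class1",
                lambda: (lambda tr: (tr[0], tr[0].n_sites))(
                    filter_class1(table, config.localization_threshold)
                ),
                n_in=n0,
                params={"threshold": config.localization_threshold},
            )
        table = runner.run(
            "vsn_transform",
            lambda: ((t := vsn_transform(table)), t.n_sites),
            n_in=table.n_sites,
        )
        if not config.filter_first:
            table = runner.run(
                "filter_class1",
                lambda: (lambda tr: (tr[0], tr[0].n_sites))(
                    filter_class1(table, config.localization_threshold)
                ),
                n_in=table.n_sites,
                params={"threshold": config.localization_threshold},
            )
        table = runner.run(
            "batch_correct",
            lambda: ((t := batch_correct(table)), t.n_sites),
            n_in=table.n_sites,
        )
        diff_cfg = DifferentialConfig(s0=config.s0, fdr=config.fdr)
        diff = runner.run(
            "sam_test",
            lambda: ((d := sam_test(table, config.contrast, diff_cfg)), int(d["tested"].sum())),
            n_in=table.n_sites,
            params={"s0": config.s0, "fdr": config.fdr, "contrast": list(config.contrast)},
        )

        def _write_diff():
            out = diff.join(table.sites[["protein", "position"]])
            path = out_dir / "differential.tsv"
            written.append(path)
            pio._write_lines(path, out.reset_index(), "\t", header)
            return out, int(diff["significant"].sum())

        runner.run("write_differential", _write_diff, n_in=len(diff))

        if config.functional_scores is not None:

            def _pafs():
                scores = pio.read_scores_tsv(config.functional_scores)
                ranked = pafs_rank(diff, table.sites, scores, config.score_threshold)
                path = out_dir / "pafs.tsv"
                written.append(path)
                pio._write_lines(path, ranked.reset_index(), "\t", header)
                return ranked, int(ranked["selected"].sum()) if len(ranked) else 0

            runner.run(
                "pafs",
                _pafs,
                n_in=int(diff["significant"].sum()),
                params={"threshold": config.score_threshold},
            )

        if config.kinase_map is not None:

            def _ksea():
                kmap = pio.read_kinase_map_tsv(config.kinase_map)
                res = ksea(diff, table.sites, kmap, config.min_substrates)
                path = out_dir / "ksea.tsv"
                written.append(path)
                pio._write_lines(path, res, "\t", header)
                return res, len(res)

            runner.run("ksea", _ksea, n_in=len(diff), params={"min_substrates": config.min_substrates})

        if "window" in table.sites.columns:

            def _motif():
                sig = diff["significant"]
                fg = table.sites.loc[sig, "window"].tolist()
                bg = table.sites["window"].tolist()
                if not fg:
                    return pd.DataFrame(), 0
                res = motif_enrichment(fg, bg, alpha=config.motif_alpha)
                path = out_dir / "motif.tsv"
                written.append(path)
                pio._write_lines(path, res, "\t", header)
                return res, int(res["enriched"].sum()) if len(res) else 0

            runner.run("motif", _motif, n_in=int(diff["significant"].sum()),
                       params={"alpha": config.motif_alpha})

    (out_dir / "run_log.json").write_text(log.to_json())
    return log
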