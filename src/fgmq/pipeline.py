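"""End-to-end pipeline: simulate/ingest -> pool -> preprocess -> metrics ->
model -> estimates, with a reproducibility manifest.

Every stage writes its outputs as CSV into the run directory and logs a
stage-tagged line to stderr.  Identical configuration and seed give
byte-identical tables; the manifest records the configuration hash, seed,
input/output digests and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from . import design, estimates, io, pooling, preprocess, quality, simulate

STAGES = ("simulate", "pool", "preprocess", "metrics", "model", "estimates")


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage
        self.cause = exc


def _log(stage: str, msg: str):
    print(f"[fgmq:{stage}] {msg}", file=sys.stderr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _build_generator(config: dict) -> simulate.GeneratorConfig:
    sim = config.get("simulate", {}) or {}
    if sim.get("preset", None) in ("paper_like", None):
        return simulate.preset_paper_like(scale=float(sim.get("scale", 1.0)))
    raise ValueError(f"unknown simulation preset {sim.get('preset')!r}")


class PipelineRun:
    """One pipeline execution rooted at ``out_dir``.

    Stages can run in one process (``run(stages=None)`` runs them all) or
    individually across processes: each stage loads what it needs from the
    run directory if the in-memory result is absent.
    """

    def __init__(self, config: dict, seed: int | None, out_dir):
        self.config = dict(config or {})
        self.seed = seed
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "config_hash": _config_hash(self.config),
            "seed": seed,
            "inputs": {},
            "outputs": {},
            "stage_rows": {},
            "timestamps": {},
            "package": "fgmq",
        }
        self._mem: dict[str, pd.DataFrame] = {}

    # -- helpers -------------------------------------------------------------
    def _write(self, name: str, frame: pd.DataFrame, microdata: bool = False):
        path = self.out_dir / name
        if microdata:
            io.write_microdata(frame, path)
        else:
            io.write_table(frame, path)
        self.manifest["outputs"][name] = _sha256(path)
        return path

    def _need(self, key: str, filename: str, microdata: bool = False) -> pd.DataFrame:
        if key in self._mem:
            return self._mem[key]
        path = self.out_dir / filename
        if not path.exists():
            raise FileNotFoundError(f"needs {filename}; run the producing stage first")
        frame = io.read_microdata_any(path) if microdata else pd.read_csv(path)
        self._mem[key] = frame
        return frame

    def _load_data(self) -> pd.DataFrame:
        """Microdata: in-memory, else the config's input file, else data.csv."""
        if "data" in self._mem:
            return self._mem["data"]
        path = self.config.get("input", None)
        if path:
            records, rejects = io.read_microdata(path)
            if len(rejects):
                _log("ingest", f"rejected {len(rejects)} rows from {path}")
            self.manifest["inputs"]["microdata"] = _sha256(path)
            self._mem["data"] = records
            return records
        return self._need("data", "data.csv", microdata=True)

    # -- stages --------------------------------------------------------------
    def stage_simulate(self):
        gen = _build_generator(self.config)
        records, truth = simulate.generate(gen, seed=self.seed)
        self._mem["data"] = records
        self._write("data.csv", records, microdata=True)
        tr = truth.frame.copy()
        tr.insert(0, "row", tr.index)
        self._write("truth.csv", tr)
        self._write("totals.csv", gen.totals_frame())
        self.manifest["stage_rows"]["simulate"] = len(records)
        _log("simulate", f"{len(records)} records across {len(gen.surveys)} surveys")

    def stage_pool(self):
        records = self._load_data()
        totals_path = self.config.get("totals", None)
        if totals_path:
            totals = io.read_population_totals(totals_path)
            self.manifest["inputs"]["totals"] = _sha256(totals_path)
        elif (self.out_dir / "totals.csv").exists():
            totals = io.read_population_totals(self.out_dir / "totals.csv")
        else:
            raise FileNotFoundError("no population totals: set 'totals' or run simulate")
        pooled = pooling.denormalize(
            records, totals, by_module=bool(self.config.get("totals_by_module", False))
        )
        self._mem["pooled"] = pooled.records
        self._write("pooled.csv", pooled.records, microdata=True)
        self._write("pooling_provenance.csv", pooled.provenance)
        self.manifest["stage_rows"]["pool"] = len(pooled.records)
        _log("pool", f"weight sums: {pooled.provenance['weight_sum'].sum():.0f} persons")

    def stage_preprocess(self):
        pooled = self._need("pooled", "pooled.csv", microdata=True)
        kept, audit = preprocess.exclude_inconsistent(pooled)
        red = preprocess.InfancyRedistributor(
            mode=self.config.get("infancy_mode", "fractional"),
            max_age=int(self.config.get("infancy_max_age", 5)),
            random_state=self.seed,
        )
        clean = red.fit_transform(kept)
        self._mem["clean"] = clean
        self._write("preprocessed.csv", clean, microdata=True)
        self._write("exclusion_audit.csv", audit.frame())
        self.manifest["stage_rows"]["preprocess"] = len(clean)
        _log("preprocess", f"excluded {audit.n_excluded_inconsistent} inconsistent records; "
             f"{sum(p.n_redistributed for p in red.plans_.values())} infancy answers redistributed")

    def stage_metrics(self):
        clean = self._need("clean", "preprocessed.csv", microdata=True)
        prof = quality.completeness_profile(clean, group_by="age_x_module")
        self._write("completeness.csv", prof)
        self._write("fig2_data.csv", prof)
        heap = quality.heaping_index(clean)
        self._write("heaping.csv", heap)
        fig3 = quality.weighted_age_counts(clean, by=["module", "survey_id"])
        self._write("fig3_data.csv", fig3)
        self.manifest["stage_rows"]["metrics"] = len(prof)
        _log("metrics", f"heaping ratios: {heap.set_index(['module', 'age'])['ratio'].round(2).to_dict()}")

    def stage_model(self):
        clean = self._need("clean", "preprocessed.csv", microdata=True)
        _, table, info = design.completeness_model(clean)
        self._write("table5.csv", table)
        self.manifest["stage_rows"]["model"] = info["n_used"]
        _log("model", f"n={info['n_used']} (dropped {info['n_dropped']}), "
             f"{info['n_psus']} PSUs / {info['n_strata']} strata")

    def stage_estimates(self):
        clean = self._need("clean", "preprocessed.csv", microdata=True)
        data = self._load_data()
        tables = estimates.composition_tables(data)
        tables["table6"] = estimates.median_table(clean)
        for name, frame in tables.items():
            self._write(f"{name}.csv", frame)
        self.manifest["stage_rows"]["estimates"] = sum(len(f) for f in tables.values())
        _log("estimates", f"wrote {', '.join(sorted(tables))}")

    # -- driver --------------------------------------------------------------
    def run(self, stages=None) -> dict:
        stages = list(stages or STAGES)
        for stage in stages:
            self.manifest["timestamps"][stage] = time.strftime("%Y-%m-%dT%H:%M:%S")
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:  # surface the failing stage by name
                raise StageError(stage, exc) from exc
        manifest_path = self.out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return self.manifest


def run_pipeline(config: dict, seed: int | None, out_dir, stages=None) -> dict:
    """Run the pipeline (all stages by default) and return the manifest."""
    return PipelineRun(config, seed, out_dir).run(stages=stages)
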