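"""Configuration, format readers/writers, and the end-to-end pipeline.

On-disk formats are plain text: counts/CPM as TSV (rows = transcript ids,
columns = sample ids), design and physiology as CSV, network edge lists as
Cytoscape-importable TSV, symbiosis parameters as flat YAML/JSON keyed by the
model symbol names, trajectories as CSV. All readers validate structure
(unique transcript ids, numeric cells, non-empty input) and raise
:class:`~coralmeta.errors.DataError` naming the offending id or line.

A single global seed fans out to per-stage child seeds by stable derivation
(numpy SeedSequence spawning) so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .simulate import COMPARTMENTS, ExpressionMatrix
from .symbiosis import SymbiosisParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Stage parameters; defaults are the analysis constants of the study
    design: strict |logFC| > 1 with p ≤ 1e-4 (coral, Symbiodiniaceae) and
    1e-3 (prokaryotes), edge filter p ≤ 0.05, top-20 core transcripts,
    blocks of 10 over 100 runs with 95/70 retention thresholds.
    """

    seed: int = 0
    synthetic: bool = True
    # synthetic-data stage
    n_reps: int = 4
    n_transcripts: dict = field(
        default_factory=lambda: {"coral": 300, "symbiodiniaceae": 120, "prokaryote": 50}
    )
    de_fraction: float = 0.1
    effect_size_log2: float = 2.0
    dispersion: float = 0.02
    drivers_per_response: int = 1
    random_effect_sd: float = 0.3
    noise_sd: float = 0.3
    # DE stage
    logfc_cutoff: float = 1.0
    p_thresholds: dict = field(
        default_factory=lambda: {"coral": 1e-4, "symbiodiniaceae": 1e-4, "prokaryote": 1e-3}
    )
    # network stage
    alpha: float = 0.05
    k_core: int = 20
    # selection stage
    n_per_fit: int = 10
    n_runs: int = 100
    threshold_runs: dict = field(
        default_factory=lambda: {"coral": 95, "prokaryote": 70}
    )
    # input paths (used when synthetic is False)
    counts_paths: dict = field(default_factory=dict)
    design_path: str | None = None
    physiology_path: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """sha256 of the canonical JSON serialization."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Stable child seeds (< 2^31) derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


# ------------------------------------------------------------- readers

def _read_table(path, sep: str, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=index_col)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty input file: {path}") from None
    if df.empty and df.columns.empty:
        raise DataError(f"empty input file: {path}")
    return df


def read_matrix_tsv(path, compartment: str = "coral", unit: str = "count") -> ExpressionMatrix:
    df = _read_table(path, sep="\t")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise DataError(f"duplicate transcript id {dup[0]!r} in {path}")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.any().any():
        i = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise DataError(
            f"non-numeric cell at line {i + 2} (transcript {df.index[i]!r}) in {path}"
        )
    if num.isna().any().any():
        i = int(np.argmax(num.isna().any(axis=1).to_numpy()))
        raise DataError(f"missing value at line {i + 2} in {path}")
    num.index.name = None  # the label is an on-disk detail, not data
    return ExpressionMatrix(compartment=compartment, unit=unit, data=num)


def write_matrix_tsv(mat: ExpressionMatrix, path) -> None:
    mat.data.to_csv(path, sep="\t", index_label="transcript_id")


def read_design_csv(path) -> pd.DataFrame:
    df = _read_table(path, sep=",", index_col=None)
    required = {"sample_id", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"design lacks columns {sorted(missing)} in {path}")
    return df


def write_design_csv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_physiology_csv(path) -> pd.DataFrame:
    df = _read_table(path, sep=",", index_col=None)
    if "sample_id" not in df.columns:
        raise DataError(f"physiology table lacks sample_id column in {path}")
    return df


def write_physiology_csv(physio: pd.DataFrame, path) -> None:
    physio.to_csv(path, index=False)


def read_edges_tsv(path) -> pd.DataFrame:
    return _read_table(path, sep="\t", index_col=None)


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_params(path) -> SymbiosisParams:
    """Flat YAML/JSON parameter file keyed by the model symbol names."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"parameter file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise DataError(f"empty parameter file: {path}")
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise DataError(f"parameter file must be a flat mapping: {path}")
    return SymbiosisParams.from_dict(raw)


def write_params(params: SymbiosisParams, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(params.to_dict(), indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(params.to_dict()), encoding="utf-8")


def read_trajectory_csv(path) -> pd.DataFrame:
    df = _read_table(path, sep=",", index_col=None)
    missing = {"t", "H", "S", "B"} - set(df.columns)
    if missing:
        raise DataError(f"trajectory lacks columns {sorted(missing)} in {path}")
    return df


def write_trajectory_csv(t: np.ndarray, states: np.ndarray, path) -> None:
    pd.DataFrame(
        {"t": t, "H": states[:, 0], "S": states[:, 1], "B": states[:, 2]}
    ).to_csv(path, index=False)


# ------------------------------------------------------------- pipeline

def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """simulate-data → de → ordination → network → select, with a manifest.

    Returns the manifest dict (also written to ``manifest.json``). Stage
    failures propagate after the manifest records which stages completed.
    """
    from . import __version__, coexpr, diffexpr, selection, simulate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }

    def _done(stage, paths):
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][str(Path(p).name)] = _file_digest(p)

    try:
        # ---- data stage
        if config.synthetic:
            design = simulate.generate_design(config.n_reps, seed=seeds[0])
            rng = np.random.default_rng(seeds[0])
            matrices, truth = simulate.generate_counts(
                design,
                n_transcripts=config.n_transcripts,
                de_fraction=config.de_fraction,
                effect_size_log2=config.effect_size_log2,
                dispersion=config.dispersion,
                seed=seeds[1],
            )
            driver_spec = {}
            pools = {
                "density": matrices["coral"].transcripts,
                "photosynthesis": matrices["coral"].transcripts,
                "respiration": matrices["prokaryote"].transcripts,
            }
            for resp, pool in pools.items():
                picks = rng.choice(
                    len(pool), size=min(config.drivers_per_response, len(pool)), replace=False
                )
                sign = 1.0 if resp != "respiration" else -1.0
                driver_spec[resp] = [(pool[i], sign) for i in picks]
            physio, oxygen, truth = simulate.generate_physiology(
                design,
                matrices,
                driver_spec=driver_spec,
                random_effect_sd=config.random_effect_sd,
                noise_sd=config.noise_sd,
                seed=seeds[2],
                truth=truth,
            )
            paths = []
            for comp, mat in matrices.items():
                p = outdir / f"counts_{comp}.tsv"
                write_matrix_tsv(mat, p)
                paths.append(p)
            write_design_csv(design, outdir / "design.csv")
            write_physiology_csv(physio, outdir / "physiology.csv")
            oxygen.to_csv(outdir / "oxygen.csv", index=False)
            truth.to_json(outdir / "ground_truth.json")
            paths += [
                outdir / "design.csv",
                outdir / "physiology.csv",
                outdir / "oxygen.csv",
                outdir / "ground_truth.json",
            ]
            _done("simulate-data", paths)
        else:
            for comp in COMPARTMENTS:
                if comp not in config.counts_paths:
                    raise ConfigError(f"no counts path configured for {comp!r}")
                if not Path(config.counts_paths[comp]).exists():
                    raise ConfigError(
                        f"counts file not found: {config.counts_paths[comp]}"
                    )
            matrices = {
                comp: read_matrix_tsv(config.counts_paths[comp], comp, "count")
                for comp in COMPARTMENTS
            }
            design = read_design_csv(config.design_path)
            physio = read_physiology_csv(config.physiology_path)
            manifest["stages"]["load-data"] = "ok"

        # ---- DE stage
        cpms, dets = {}, {}
        paths = []
        for comp, mat in matrices.items():
            cpm_mat = diffexpr.cpm(mat)
            cpms[comp] = cpm_mat
            tables = [
                diffexpr.pairwise_de(cpm_mat, design, t)
                for t in ("5", "10", "20", "40")
            ]
            de = pd.concat(tables, ignore_index=True)
            p = outdir / f"de_{comp}.tsv"
            de.to_csv(p, sep="\t", index=False)
            paths.append(p)
            dets[comp] = diffexpr.call_dets(de, comp)
        venn = {c: d.venn_counts for c, d in dets.items()}
        (outdir / "venn_counts.json").write_text(json.dumps(venn, indent=2))
        paths.append(outdir / "venn_counts.json")
        _done("de", paths)

        # ---- ordination stage
        paths = []
        for comp, cpm_mat in cpms.items():
            det_ids = sorted(dets[comp].union)
            if not det_ids:
                continue
            sub = ExpressionMatrix(comp, "cpm", cpm_mat.data.loc[det_ids])
            diss = diffexpr.bray_curtis(diffexpr.ordination_transform(sub))
            p = outdir / f"braycurtis_{comp}.csv"
            diss.to_csv(p)
            paths.append(p)
        _done("ordination", paths)

        # ---- network stage
        paths = []
        sample_order = design["sample_id"].tolist()
        logexpr = {
            comp: np.log2(cpms[comp].data[sample_order] + 1.0) for comp in COMPARTMENTS
        }
        networks = {}
        for name, (ca, cb) in coexpr.NETWORK_PAIRS.items():
            ids_a, ids_b = sorted(dets[ca].union), sorted(dets[cb].union)
            if not ids_a or not ids_b:
                logger.warning("network %s skipped: empty DET set", name)
                continue
            edges, n_pairs = coexpr.correlate_pairs(
                logexpr[ca].loc[ids_a], logexpr[cb].loc[ids_b]
            )
            net = coexpr.build_network(edges, n_pairs, name=name, alpha=config.alpha)
            networks[name] = net
            pe = outdir / f"edges_{name}.tsv"
            write_edges_tsv(coexpr.edge_table(net), pe)
            pn = outdir / f"nodes_{name}.tsv"
            coexpr.node_table(net, config.k_core).to_csv(pn, sep="\t", index=False)
            paths += [pe, pn]
        _done("network", paths)

        # ---- selection stage
        # aquarium-level grouping: one aquarium per sample in this design
        group = design["sample_id"].to_numpy()
        resp_cols = {"density": "density", "photosynthesis": "p_net", "respiration": "r_dark"}
        results = []
        sel_seeds = stage_seeds(seeds[3], n=2 * len(resp_cols))
        k = 0
        for comp, thr in (("coral", config.threshold_runs["coral"]),
                          ("prokaryote", config.threshold_runs["prokaryote"])):
            predictors = logexpr[comp].T
            for resp, col in resp_cols.items():
                res = selection.repeated_selection(
                    physio.set_index("sample_id").loc[sample_order, col].to_numpy(),
                    predictors,
                    group,
                    response_name=f"{comp}:{resp}",
                    n_per_fit=config.n_per_fit,
                    n_runs=config.n_runs,
                    threshold_runs=thr,
                    seed=sel_seeds[k % len(sel_seeds)],
                )
                k += 1
                results.append(res)
        retention = pd.concat([r.to_frame() for r in results], ignore_index=True)
        p = outdir / "retention.tsv"
        retention.to_csv(p, sep="\t", index=False)
        summary = selection.summarize_selection(results)
        ps = outdir / "selection_summary.tsv"
        summary.to_csv(ps, sep="\t", index=False)
        _done("select", [p, ps])
    except Exception:
        manifest["stages"]["failed"] = True
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
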