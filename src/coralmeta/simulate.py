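"""Synthetic tri-compartment data with known planted structure.

Emulates a nitrate-enrichment larval experiment: five treatment levels
(ambient control at 2.5 µM plus 5, 10, 20, 40 µM nitrate) with replicate
aquaria, negative-binomial expression counts for the three holobiont
compartments (coral host, Symbiodiniaceae, prokaryotes), and Symbiodiniaceae
physiology (cell density, net photosynthesis, dark respiration) driven by
named transcripts plus an aquarium-level random intercept.

Everything is generated from a single integer seed and is bit-reproducible.
The planted structure (differentially expressed transcripts, cross-compartment
correlated pairs, physiology driver transcripts) is recorded in a
:class:`GroundTruth` so downstream stages can be scored against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, SpecificationError

# Nitrate levels in µM; the first is the ambient control.
NITRATE_LEVELS: tuple[float, ...] = (2.5, 5.0, 10.0, 20.0, 40.0)
CONTROL_LEVEL: float = 2.5
TREATMENT_LABELS: tuple[str, ...] = ("control", "5", "10", "20", "40")

COMPARTMENTS: tuple[str, ...] = ("coral", "symbiodiniaceae", "prokaryote")
_PREFIX = {"coral": "coral", "symbiodiniaceae": "symb", "prokaryote": "prok"}

#: Treatment-vs-control comparison labels, in nitrate order.
COMPARISONS: tuple[str, ...] = tuple(
    f"control_vs_{lbl}" for lbl in TREATMENT_LABELS[1:]
)

#: Default transcript counts per compartment; chosen to mirror the relative
#: DET magnitudes of the three compartments (hundreds / ~hundred / tens) so
#: that downstream network sizes are comparable across compartments.
DEFAULT_N_TRANSCRIPTS: dict[str, int] = {
    "coral": 300,
    "symbiodiniaceae": 120,
    "prokaryote": 50,
}

RESPONSES: tuple[str, ...] = ("density", "photosynthesis", "respiration")

#: Natural-scale intercept and scale (response units per standardized unit)
#: for each physiology response: density in cells per larva (centred inside
#: the observed 1.6e4–1.9e4 range), rates in nmol O2 larva^-1 min^-1.
RESPONSE_SCALES: dict[str, tuple[float, float]] = {
    "density": (1.75e4, 5.0e2),
    "photosynthesis": (1.0, 0.15),
    "respiration": (0.5, 0.08),
}


@dataclass
class ExpressionMatrix:
    """Transcripts × samples expression values for one compartment.

    ``unit`` is ``"count"`` (nonnegative integers) or ``"cpm"`` (columns sum
    to 1e6 whenever any count is positive).
    """

    compartment: str
    unit: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ConfigError(f"unknown compartment {self.compartment!r}")
        if self.unit not in ("count", "cpm"):
            raise ConfigError(f"unknown unit {self.unit!r}")
        if (self.data.values < 0).any():
            raise ConfigError("expression values must be nonnegative")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ConfigError(f"duplicate transcript id {dup!r}")

    @property
    def transcripts(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset.

    de_transcripts: compartment -> comparison -> transcript id -> true log2FC.
    correlated_pairs: (transcript_a, transcript_b, latent loading) triples;
        the two transcripts always live in different compartments.
    physio_drivers: response -> transcript id -> true standardized coefficient.
    """

    seed: int
    de_transcripts: dict = field(default_factory=dict)
    correlated_pairs: list = field(default_factory=list)
    physio_drivers: dict = field(default_factory=dict)

    def de_union(self, compartment: str) -> set[str]:
        """Planted transcripts that are DE in at least one comparison."""
        out: set[str] = set()
        for per_tid in self.de_transcripts.get(compartment, {}).values():
            out.update(per_tid)
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


def generate_design(n_reps: int = 4, seed: int = 0) -> pd.DataFrame:
    """Balanced design: 5 nitrate levels × ``n_reps`` replicate aquaria.

    Returns a DataFrame with columns ``sample_id``, ``treatment`` (label,
    "control" for the ambient 2.5 µM level), ``nitrate_uM``, ``replicate``.
    Deterministic given the seed (the layout itself carries no randomness;
    the seed is recorded for provenance).
    """
    if n_reps < 2:
        raise DesignError("need at least 2 replicate aquaria per treatment")
    rows = []
    for level, label in zip(NITRATE_LEVELS, TREATMENT_LABELS):
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{'ctrl' if label == 'control' else 'n' + label}_r{rep}",
                    "treatment": label,
                    "nitrate_uM": level,
                    "replicate": rep,
                }
            )
    design = pd.DataFrame(rows)
    design.attrs["seed"] = int(seed)
    return design


def _validate_design(design: pd.DataFrame) -> None:
    required = {"sample_id", "treatment", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise DesignError(f"design lacks columns: {sorted(missing)}")
    if design.duplicated(["treatment", "replicate"]).any():
        raise DesignError("duplicate (treatment, replicate) pair in design")
    if "control" not in set(design["treatment"]):
        raise DesignError("design has no control level")


def _transcript_ids(compartment: str, n: int) -> list[str]:
    p = _PREFIX[compartment]
    return [f"{p}_t{i:04d}" for i in range(n)]


def generate_counts(
    design: pd.DataFrame,
    n_transcripts: Mapping[str, int] | None = None,
    de_fraction: float = 0.0,
    effect_size_log2: float = 2.0,
    dispersion: float = 0.02,
    corr_block_spec: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
    *,
    lib_size: float = 2.0e6,
    lib_sigma: float = 0.15,
    baseline_sigma: float = 1.0,
    de_treatments: str = "all",
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Negative-binomial counts for the three compartments.

    Per-transcript baseline abundances are log-normal; per-sample library
    sizes are log-normal around ``lib_size``. A fraction ``de_fraction`` of
    transcripts per compartment is planted as differentially expressed with
    log2 fold change ``±effect_size_log2`` (random sign) in the treatments
    selected by ``de_treatments`` ("all" → every non-control level). Entries
    of ``corr_block_spec`` are ``(tid_a, tid_b, loading)``: the two
    transcripts share a per-sample standard-normal latent factor added to
    their log2 mean with the given loading, which induces a positive
    (or, for opposite-sign loadings encoded as negative values, negative)
    cross-compartment correlation.

    Counts are gamma–Poisson draws, i.e. NB with variance mu + dispersion*mu².
    """
    _validate_design(design)
    if n_transcripts is None:
        n_transcripts = DEFAULT_N_TRANSCRIPTS
    for comp in COMPARTMENTS:
        if n_transcripts.get(comp, 0) < 50:
            raise ConfigError(f"need >= 50 transcripts per compartment ({comp})")
    if dispersion <= 0:
        raise ConfigError("dispersion must be > 0")
    if de_fraction > 0 and abs(effect_size_log2) <= 1:
        raise ConfigError(
            "|effect_size_log2| must exceed 1 so planted DE transcripts are "
            "discoverable under the |logFC| > 1 rule"
        )

    rng = np.random.default_rng(seed)
    samples = design["sample_id"].tolist()
    n_samples = len(samples)
    treatments = design["treatment"].to_numpy()

    all_ids = {
        comp: _transcript_ids(comp, int(n_transcripts[comp]))
        for comp in COMPARTMENTS
    }
    id_to_comp = {tid: comp for comp, ids in all_ids.items() for tid in ids}
    for a, b, _ in corr_block_spec:
        for tid in (a, b):
            if tid not in id_to_comp:
                raise SpecificationError(f"unknown transcript id {tid!r} in corr_block_spec")

    truth = GroundTruth(seed=int(seed))
    # Latent factors: one standard-normal per correlated pair and sample.
    latents = {
        idx: rng.standard_normal(n_samples)
        for idx in range(len(corr_block_spec))
    }
    truth.correlated_pairs = [list(t) for t in corr_block_spec]

    de_labels = (
        TREATMENT_LABELS[1:]
        if de_treatments == "all"
        else tuple(de_treatments)
    )

    matrices: dict[str, ExpressionMatrix] = {}
    for comp in COMPARTMENTS:
        ids = all_ids[comp]
        n_t = len(ids)
        baseline = rng.lognormal(mean=np.log(200.0), sigma=baseline_sigma, size=n_t)
        weights = baseline / baseline.sum()
        libs = rng.lognormal(mean=np.log(lib_size), sigma=lib_sigma, size=n_samples)
        log2_shift = np.zeros((n_t, n_samples))

        # planted differential expression
        n_de = int(round(de_fraction * n_t))
        de_idx = rng.choice(n_t, size=n_de, replace=False)
        truth.de_transcripts[comp] = {c: {} for c in COMPARISONS}
        for i in de_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * effect_size_log2
            for lbl in de_labels:
                mask = treatments == lbl
                log2_shift[i, mask] += lfc
                truth.de_transcripts[comp][f"control_vs_{lbl}"][ids[i]] = lfc

        # shared latent factors (cross-compartment correlation)
        for k, (a, b, loading) in enumerate(corr_block_spec):
            for tid in (a, b):
                if id_to_comp[tid] == comp:
                    i = ids.index(tid)
                    log2_shift[i, :] += loading * latents[k]

        mu = weights[:, None] * libs[None, :] * np.exp2(log2_shift)
        shape = 1.0 / dispersion
        counts = rng.poisson(rng.gamma(shape, mu / shape))
        matrices[comp] = ExpressionMatrix(
            compartment=comp,
            unit="count",
            data=pd.DataFrame(counts, index=ids, columns=samples),
        )
    return matrices, truth


def _normalize_driver_spec(
    driver_spec: Mapping[str, Iterable] | None,
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {r: {} for r in RESPONSES}
    if driver_spec is None:
        return out
    for resp, entries in driver_spec.items():
        if resp not in RESPONSES:
            raise ConfigError(f"unknown physiology response {resp!r}")
        for entry in entries:
            if isinstance(entry, str):
                tid, beta = entry, 1.0
            else:
                tid, beta = entry
            out[resp][tid] = float(beta)
    return out


def generate_physiology(
    design: pd.DataFrame,
    matrices: Mapping[str, ExpressionMatrix],
    driver_spec: Mapping[str, Iterable] | None = None,
    random_effect_sd: float = 0.3,
    noise_sd: float = 0.3,
    seed: int = 0,
    *,
    truth: GroundTruth | None = None,
    n_measurements: int = 1,
    n_larvae: int = 20,
    o2_baseline_nmol: float = 500.0,
    o2_noise_nmol: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Symbiodiniaceae physiology as linear functions of transcript CPMs.

    Each response (cells-per-larva density, net photosynthesis P_N, dark
    respiration R_D) is ``intercept + scale * (Σ β_t z_t + u + ε)`` where
    ``z_t`` is the standardized log2(CPM+1) of a driver transcript, ``u`` an
    aquarium-level random intercept with sd ``random_effect_sd`` and ``ε``
    residual noise with sd ``noise_sd`` (both in standardized units; ``scale``
    converts to natural units). ``n_measurements`` > 1 yields repeated
    measurements per aquarium sharing the same random intercept, which makes
    the intraclass correlation estimable.

    Also returns oxygen time series: straight 10-min lines whose chamber
    slopes are ``±rate × n_larvae`` (light: P_N, dark: −R_D) plus observation
    noise, with matching zero-slope blank chambers.
    """
    _validate_design(design)
    rng = np.random.default_rng(seed)
    spec = _normalize_driver_spec(driver_spec)

    # standardized log2(CPM+1) per driver transcript
    from .diffexpr import cpm  # local import: avoids a hard cycle at import time

    logcpm: dict[str, np.ndarray] = {}
    samples = design["sample_id"].tolist()
    for comp, mat in matrices.items():
        mat_cpm = mat if mat.unit == "cpm" else cpm(mat)
        sub = mat_cpm.data[samples]
        z = np.log2(sub.to_numpy(dtype=float) + 1.0)
        sd = z.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=1, keepdims=True)) / sd[:, None]
        for i, tid in enumerate(sub.index):
            logcpm[tid] = z[i]
    for resp, drivers in spec.items():
        for tid in drivers:
            if tid not in logcpm:
                raise SpecificationError(f"unknown driver transcript {tid!r}")

    if truth is None:
        truth = GroundTruth(seed=int(seed))
    truth.physio_drivers = {r: dict(d) for r, d in spec.items()}

    n = len(samples)
    u = {r: rng.normal(0.0, random_effect_sd, size=n) for r in RESPONSES}

    rows = []
    for m in range(1, n_measurements + 1):
        eps = {r: rng.normal(0.0, noise_sd, size=n) for r in RESPONSES}
        rec: dict[str, np.ndarray] = {}
        for resp in RESPONSES:
            intercept, scale = RESPONSE_SCALES[resp]
            lin = np.zeros(n)
            for tid, beta in spec[resp].items():
                lin += beta * logcpm[tid]
            rec[resp] = intercept + scale * (lin + u[resp] + eps[resp])
        df = pd.DataFrame(
            {
                "sample_id": samples,
                "measurement": m,
                "density": np.maximum(rec["density"], 0.0),
                "p_net": rec["photosynthesis"],
                "r_dark": np.maximum(rec["respiration"], 0.0),
            }
        )
        rows.append(df)
    physio = pd.concat(rows, ignore_index=True)
    if n_measurements == 1:
        physio = physio.drop(columns="measurement")

    # oxygen time series for the first measurement of each sample
    first = physio.groupby("sample_id", sort=False).first().reindex(samples)
    times = np.arange(0.0, 11.0)  # 0..10 min
    o2_rows = []
    for sid in samples:
        pn = float(first.loc[sid, "p_net"])
        rd = float(first.loc[sid, "r_dark"])
        for phase, rate in (("light", pn), ("dark", -rd)):
            slope = rate * n_larvae
            for is_blank in (False, True):
                s = 0.0 if is_blank else slope
                o2 = o2_baseline_nmol + s * times + rng.normal(0, o2_noise_nmol, times.size)
                for t, v in zip(times, o2):
                    o2_rows.append(
                        {
                            "sample_id": sid,
                            "phase": phase,
                            "time_min": t,
                            "o2_nmol": v,
                            "is_blank": is_blank,
                            "n_larvae": n_larvae,
                        }
                    )
    oxygen = pd.DataFrame(o2_rows)
    return physio, oxygen, truth
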