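"""Seeded synthetic prescription datasets with planted ground truth.

The generator emulates a virtual-diagnosis study: a panel of practitioners
(80 by default) each prescribes an acupoint set for every one of 10 clinical
cases, and the cases fall into three latent disease clusters. Four disjoint
acupoint pools drive each prescription, every pool member being included
independently (Bernoulli):

* a shared **core** set prescribed across all cases (p_core = 0.6) — the
  broadly indicated points every practitioner reaches for;
* **cluster-specific** points shared by the cases of one disease cluster
  (p_cluster = 0.4), e.g. local knee/back points for the musculoskeletal
  cluster;
* one **case-specific** point per case (p_case = 0.5) — the signature of the
  individual vignette;
* a sparse **background** pool (p_bg = 0.05) modelling idiosyncratic picks.

Prescription sizes outside the configured range (3-12 points) are handled by
resampling only the background inclusions, then by deterministic
lexicographic truncation/padding, so the planted structure is never
disturbed by the size constraint.

The default vocabulary is exactly 30 distinct acupoints, so the top-30
analysis set always contains every planted point and recovery tests measure
the statistics, not a lottery over which rare point enters the top-30 (a
background and a case-specific point have the same expected total count
under the default rates, so any larger vocabulary would make top-30
membership of planted points a coin flip).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .ingest import PrescriptionRecord, build_count_matrix, is_valid_code

__all__ = ["SyntheticConfig", "PlantedTruth", "generate",
           "planted_truth_report", "records_to_csv"]

_DEFAULT_CASES = tuple(f"case{i}" for i in range(1, 11))
_DEFAULT_CLUSTER_MAP = {
    "case4": "A", "case6": "A", "case8": "A",
    "case3": "B", "case7": "B", "case9": "B",
    "case1": "C", "case2": "C", "case5": "C", "case10": "C",
}
_DEFAULT_CORE = ("CV12", "LI4", "LR3", "PC6", "SP6", "ST36")
_DEFAULT_CLUSTER_SPECIFIC = {
    "A": ("BL23", "GB34", "SP10", "ST35"),   # musculoskeletal: knee + back
    "B": ("CV17", "HT7", "KI3"),             # psychiatric
    "C": ("GB20", "LU9", "SI19"),            # internal medicine
}
_DEFAULT_CASE_SPECIFIC = {
    "case1": ("GV20",),    # vertigo
    "case2": ("ST21",),    # reflux
    "case3": ("KI6",),     # climacteric
    "case4": ("EX-LE4",),  # knee injury
    "case5": ("EX-UE9",),  # neuropathy of the hands
    "case6": ("CV4",),     # pelvic pain
    "case7": ("EX-HN3",),  # panic
    "case8": ("GV3",),     # low back pain
    "case9": ("GB21",),    # fibromyalgia
    "case10": ("HT6",),    # hyperhidrosis
}
_DEFAULT_BACKGROUND = ("BL60", "GV14", "LI11", "TE5")


@dataclass
class SyntheticConfig:
    """Study-scale generator configuration (see module docstring)."""

    n_practitioners: int = 80
    case_ids: tuple[str, ...] = _DEFAULT_CASES
    cluster_map: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_CLUSTER_MAP))
    core_acupoints: tuple[str, ...] = _DEFAULT_CORE
    p_core: float = 0.6
    cluster_specific: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CLUSTER_SPECIFIC))
    p_cluster: float = 0.4
    case_specific: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CASE_SPECIFIC))
    p_case: float = 0.5
    background_pool: tuple[str, ...] = _DEFAULT_BACKGROUND
    p_bg: float = 0.05
    size_min: int = 3
    size_max: int = 12
    seed: int = 0

    def all_acupoints(self) -> list[str]:
        pools: list[str] = list(self.core_acupoints)
        for points in self.cluster_specific.values():
            pools.extend(points)
        for points in self.case_specific.values():
            pools.extend(points)
        pools.extend(self.background_pool)
        return pools

    def validate(self) -> None:
        for name, p in (("p_core", self.p_core), ("p_cluster", self.p_cluster),
                        ("p_case", self.p_case), ("p_bg", self.p_bg)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.n_practitioners < 1:
            raise ConfigError("n_practitioners must be >= 1")
        if not self.case_ids:
            raise ConfigError("case_ids must be non-empty")
        missing = set(self.case_ids) - set(self.cluster_map)
        if missing:
            raise ConfigError(f"cluster_map misses cases: {sorted(missing)}")
        clusters_used = {self.cluster_map[c] for c in self.case_ids}
        unknown = clusters_used - set(self.cluster_specific)
        if unknown:
            raise ConfigError(f"cluster_specific misses clusters: {sorted(unknown)}")
        pools = self.all_acupoints()
        if len(pools) != len(set(pools)):
            seen, dup = set(), set()
            for a in pools:
                (dup if a in seen else seen).add(a)
            raise ConfigError(f"acupoint pools must be pairwise disjoint; "
                              f"duplicated: {sorted(dup)}")
        bad = [a for a in pools if not is_valid_code(a)]
        if bad:
            raise ConfigError(f"invalid acupoint codes in pools: {bad}")
        if self.size_min < 1:
            raise ConfigError("size_min must be >= 1")
        if self.size_max < self.size_min:
            raise ConfigError("size_max must be >= size_min")
        if self.size_min > len(pools):
            raise ConfigError(
                f"size_min={self.size_min} exceeds the {len(pools)}-point pool"
            )


@dataclass
class PlantedTruth:
    """What the generator planted, for recovery tests and reports."""

    cluster_map: dict[str, str]
    core_acupoints: tuple[str, ...]
    cluster_specific: dict[str, tuple[str, ...]]
    case_specific: dict[str, tuple[str, ...]]
    background_pool: tuple[str, ...]
    config: SyntheticConfig


def _draw(rng: np.random.Generator, pool: Sequence[str], p: float) -> set[str]:
    if not pool:
        return set()
    mask = rng.random(len(pool)) < p
    return {a for a, hit in zip(pool, mask) if hit}


def generate(config: SyntheticConfig | None = None,
             seed: int | None = None
             ) -> tuple[list[PrescriptionRecord], PlantedTruth]:
    """Generate one synthetic dataset; identical (config, seed) -> identical data.

    ``seed`` overrides ``config.seed`` when given. Returns the records in
    (practitioner, case) order plus the planted truth.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        from dataclasses import replace

        config = replace(config, seed=int(seed))
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_practitioners))
    all_pool = sorted(config.all_acupoints())
    records: list[PrescriptionRecord] = []
    for p in range(1, config.n_practitioners + 1):
        pid = f"D{p:0{width}d}"
        for case_id in config.case_ids:
            cluster = config.cluster_map[case_id]
            fixed = _draw(rng, config.core_acupoints, config.p_core)
            fixed |= _draw(rng, config.cluster_specific[cluster], config.p_cluster)
            fixed |= _draw(rng, config.case_specific.get(case_id, ()), config.p_case)
            chosen = fixed | _draw(rng, config.background_pool, config.p_bg)
            attempts = 0
            while not (config.size_min <= len(chosen) <= config.size_max):
                attempts += 1
                if attempts > 100:
                    break
                chosen = fixed | _draw(rng, config.background_pool, config.p_bg)
            if len(chosen) > config.size_max:
                chosen = set(sorted(chosen)[: config.size_max])
            elif len(chosen) < config.size_min:
                for a in all_pool:
                    if len(chosen) >= config.size_min:
                        break
                    chosen.add(a)
            records.append(PrescriptionRecord(pid, case_id, frozenset(chosen)))
    truth = PlantedTruth(
        cluster_map=dict(config.cluster_map),
        core_acupoints=tuple(config.core_acupoints),
        cluster_specific={k: tuple(v) for k, v in config.cluster_specific.items()},
        case_specific={k: tuple(v) for k, v in config.case_specific.items()},
        background_pool=tuple(config.background_pool),
        config=config,
    )
    return records, truth


def planted_truth_report(records: Iterable[PrescriptionRecord],
                         truth: PlantedTruth) -> dict:
    """Planted parameters alongside realized counts and inclusion rates.

    Realized inclusion frequency for a pool acupoint is its count among the
    records where it was eligible (all records for core/background points,
    one cluster's or one case's records otherwise).
    """
    records = list(records)
    config = truth.config
    counts = build_count_matrix(records, case_order=config.case_ids)
    n_records = len(records)
    per_case = {c: sum(1 for r in records if r.case_id == c)
                for c in config.case_ids}

    def rate(acupoint: str, cases: Sequence[str]) -> float:
        eligible = sum(per_case[c] for c in cases)
        got = int(counts.loc[list(cases), acupoint].sum()) \
            if acupoint in counts.columns else 0
        return got / eligible if eligible else 0.0

    all_cases = list(config.case_ids)
    realized: dict[str, dict] = {}
    for a in truth.core_acupoints:
        realized[a] = {"pool": "core", "planted_p": config.p_core,
                       "realized_frequency": rate(a, all_cases)}
    for label, points in truth.cluster_specific.items():
        cases = [c for c in all_cases if truth.cluster_map[c] == label]
        for a in points:
            realized[a] = {"pool": f"cluster:{label}", "planted_p": config.p_cluster,
                           "realized_frequency": rate(a, cases)}
    for case_id, points in truth.case_specific.items():
        for a in points:
            realized[a] = {"pool": f"case:{case_id}", "planted_p": config.p_case,
                           "realized_frequency": rate(a, [case_id])}
    for a in truth.background_pool:
        realized[a] = {"pool": "background", "planted_p": config.p_bg,
                       "realized_frequency": rate(a, all_cases)}
    return {
        "n_records": n_records,
        "records_per_case": per_case,
        "planted_partition": dict(truth.cluster_map),
        "acupoints": realized,
        "per_case_counts": {
            case: {a: int(v) for a, v in row.items() if v}
            for case, row in counts.iterrows()
        },
        "seed": config.seed,
    }


def records_to_csv(records: Iterable[PrescriptionRecord], path,
                   token_delimiter: str = ";") -> None:
    """Write records in the ingest dialect (practitioner_id, case_id, acupoints).

    Acupoints are written in lexicographic order, so identical datasets
    produce byte-identical files.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("practitioner_id,case_id,acupoints\n")
        for rec in records:
            points = token_delimiter.join(sorted(rec.acupoints))
            fh.write(f"{rec.practitioner_id},{rec.case_id},{points}\n")


def config_to_text(config: SyntheticConfig, path=None) -> str:
    """Human-editable key-value dump of a generator configuration (JSON)."""
    payload = asdict(config)
    text = json.dumps(payload, indent=2, default=list)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
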