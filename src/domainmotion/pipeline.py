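"""End-to-end runs: multi-condition descriptor passes and mutant-cycle reports.

A run is driven by a :class:`RunConfig` (loadable from YAML) naming one or
more *conditions* — e.g. WT started from the crystallographic open state,
WT started from the modeled open state, and a mutant — each with one or more
replicate trajectories. Replicates within a condition are pooled frame-wise
for distributions (per-replicate tables are also written); conditions are
never pooled. Reports carry a content hash of the configuration so every
number is traceable to exact settings, and contain no timestamps, so reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from domainmotion import biochem
from domainmotion.biochem import ActivityRecord, VariantLabel
from domainmotion.errors import ConfigurationError, DomainMotionError, MissingAtomsError
from domainmotion.geometry import (
    DescriptorConfig,
    ca_pair_distance,
    csh2_rotation_angle,
    ionpair_occupancy,
    joint_contact_fraction,
    min_sidechain_contact_distance,
    nsh2_rotation_angle,
    residue_sasa,
    summarize,
    tandem_sh2_dihedral,
)
from domainmotion.structure_io import (
    DomainPartition,
    FrameStream,
    StructureFrame,
    read_structure,
    write_descriptor_table,
)

logger = logging.getLogger("domainmotion")


@dataclass
class Condition:
    label: str
    trajectories: list[str]
    topology: str | None = None


@dataclass
class RunConfig:
    """Validated inputs for a multi-condition descriptor run."""

    reference: str
    conditions: list[Condition]
    output_dir: str = "domainmotion_out"
    descriptor_config: DescriptorConfig = field(default_factory=DescriptorConfig)
    partition: DomainPartition = field(default_factory=DomainPartition.default_shp2)
    ionpairs: list[tuple[int, int]] = field(default_factory=lambda: [(4, 139), (5, 139)])
    ca_pair: tuple[int, int] = (32, 138)
    sasa_residue: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"condition labels are not unique: {labels}")
        if not self.conditions:
            raise ConfigurationError("at least one condition is required")

    def validate_paths(self) -> None:
        missing = [p for c in self.conditions for p in c.trajectories if not Path(p).exists()]
        if not Path(self.reference).exists():
            missing.append(self.reference)
        if missing:
            raise ConfigurationError(f"unresolvable input paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        conditions = [
            Condition(
                label=c["label"],
                trajectories=list(c["trajectories"]),
                topology=c.get("topology"),
            )
            for c in raw["conditions"]
        ]
        descriptor_config = DescriptorConfig.from_dict(raw.get("descriptor_config", {}))
        if "partition" in raw:
            # explicit residue lists per domain label
            partition = DomainPartition(raw["partition"])
        else:
            partition = DomainPartition.default_shp2()
        return cls(
            reference=raw["reference"],
            conditions=conditions,
            output_dir=raw.get("output_dir", "domainmotion_out"),
            descriptor_config=descriptor_config,
            partition=partition,
            ionpairs=[tuple(p) for p in raw.get("ionpairs", [(4, 139), (5, 139)])],
            ca_pair=tuple(raw.get("ca_pair", (32, 138))),
            sasa_residue=raw.get("sasa_residue"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )

    def content_dict(self) -> dict:
        return {
            "reference": self.reference,
            "conditions": [
                {"label": c.label, "trajectories": c.trajectories, "topology": c.topology}
                for c in self.conditions
            ],
            "descriptor_config": self.descriptor_config.to_dict(),
            "partition": {k: sorted(v) for k, v in self.partition.domains.items()},
            "ionpairs": [list(p) for p in self.ionpairs],
            "ca_pair": list(self.ca_pair),
            "sasa_residue": self.sasa_residue,
            "seed": self.seed,
        }

    def content_hash(self) -> str:
        canon = json.dumps(self.content_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Per-condition descriptor summaries, occupancies, and median differences."""

    config_hash: str
    conditions: dict  # label -> {descriptor summaries, occupancies, frame counts}
    median_differences: dict  # "A vs B" -> {descriptor: median(A) - median(B)}

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "conditions": self.conditions,
            "median_differences": self.median_differences,
        }


def frame_descriptors(
    frame: StructureFrame,
    reference: StructureFrame,
    partition: DomainPartition,
    config: DescriptorConfig,
    ionpairs: list[tuple[int, int]],
    ca_pair: tuple[int, int] = (32, 138),
    sasa_residue: int | None = None,
) -> dict[str, float]:
    """All per-frame descriptors for one frame; missing atoms yield NaN."""
    out: dict[str, float] = {}

    def _measure(name: str, fn):
        try:
            out[name] = fn()
        except (MissingAtomsError, DomainMotionError) as exc:
            logger.warning("frame %d: %s skipped (%s)", frame.frame_index, name, exc)
            out[name] = math.nan

    _measure("nsh2_rotation", lambda: nsh2_rotation_angle(frame, reference, partition, config))
    _measure("csh2_rotation", lambda: csh2_rotation_angle(frame, reference, config, partition))
    _measure("tandem_sh2_dihedral", lambda: tandem_sh2_dihedral(frame, config))
    for basic, acidic in ionpairs:
        _measure(
            f"mindist_{basic}_{acidic}",
            lambda b=basic, a=acidic: min_sidechain_contact_distance(frame, b, a),
        )
    _measure(
        f"ca_dist_{ca_pair[0]}_{ca_pair[1]}",
        lambda: ca_pair_distance(frame, ca_pair[0], ca_pair[1]),
    )
    if sasa_residue is not None:
        _measure(
            f"sasa_{sasa_residue}",
            lambda: residue_sasa(frame, sasa_residue, "sidechain", config),
        )
    return out


_UNITS = {
    "nsh2_rotation": "degrees",
    "csh2_rotation": "degrees",
    "tandem_sh2_dihedral": "degrees",
}


def _unit_for(name: str) -> str:
    if name in _UNITS:
        return _UNITS[name]
    if name.startswith("sasa_"):
        return "A^2"
    return "A"


def describe_stream(
    stream: FrameStream,
    reference: StructureFrame,
    partition: DomainPartition,
    config: DescriptorConfig,
    ionpairs: list[tuple[int, int]],
    ca_pair: tuple[int, int] = (32, 138),
    sasa_residue: int | None = None,
) -> dict[str, "np.ndarray"]:
    """Per-frame descriptor arrays for a whole trajectory."""
    rows = [
        frame_descriptors(f, reference, partition, config, ionpairs, ca_pair, sasa_residue)
        for f in stream
    ]
    names = list(rows[0])
    return {name: np.array([r[name] for r in rows]) for name in names}


def run_describe(config: RunConfig) -> ComparisonReport:
    """Descriptor pass over every condition/replicate; writes TSVs and a JSON report."""
    config.validate_paths()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = read_structure(config.reference, model_index=0)

    conditions_report: dict = {}
    pooled_by_condition: dict[str, dict[str, np.ndarray]] = {}
    for condition in config.conditions:
        pooled: dict[str, list] = {}
        n_frames_per_replicate = []
        for r, traj_path in enumerate(condition.trajectories):
            stream = read_structure(traj_path, topology=condition.topology)
            if isinstance(stream, StructureFrame):
                stream = FrameStream([stream], source=str(traj_path))
            values = describe_stream(
                stream,
                reference,
                config.partition,
                config.descriptor_config,
                config.ionpairs,
                config.ca_pair,
                config.sasa_residue,
            )
            n_frames_per_replicate.append(stream.count)
            series = [summarize(v, name, _unit_for(name)) for name, v in values.items()]
            safe_label = condition.label.replace("/", "-").replace(" ", "_")
            write_descriptor_table(series, out_dir / f"{safe_label}_rep{r + 1}.tsv")
            for name, v in values.items():
                pooled.setdefault(name, []).append(v)
        pooled_arrays = {name: np.concatenate(chunks) for name, chunks in pooled.items()}
        pooled_by_condition[condition.label] = pooled_arrays
        logger.info(
            "condition %s: pooled %d replicates (%s frames)",
            condition.label,
            len(condition.trajectories),
            n_frames_per_replicate,
        )

        occupancies = {}
        for basic, acidic in config.ionpairs:
            occupancies[f"{basic}-{acidic}"] = ionpair_occupancy(
                pooled_arrays[f"mindist_{basic}_{acidic}"],
                config.descriptor_config.ionpair_cutoff,
            )
        if len(config.ionpairs) >= 2:
            (b1, a1), (b2, a2) = config.ionpairs[:2]
            occupancies["joint"] = joint_contact_fraction(
                pooled_arrays[f"mindist_{b1}_{a1}"],
                pooled_arrays[f"mindist_{b2}_{a2}"],
                config.descriptor_config.ionpair_cutoff,
            )
        conditions_report[condition.label] = {
            "n_replicates": len(condition.trajectories),
            "n_frames": n_frames_per_replicate,
            "descriptors": {
                name: summarize(v, name, _unit_for(name)).summary()
                for name, v in pooled_arrays.items()
            },
            "occupancies": occupancies,
        }

    labels = [c.label for c in config.conditions]
    median_differences: dict = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            diffs = {}
            for name in pooled_by_condition[a]:
                if name in pooled_by_condition[b]:
                    ma = float(np.nanmedian(pooled_by_condition[a][name]))
                    mb = float(np.nanmedian(pooled_by_condition[b][name]))
                    diffs[name] = ma - mb
            median_differences[f"{a} vs {b}"] = diffs

    report = ComparisonReport(
        config_hash=config.content_hash(),
        conditions=conditions_report,
        median_differences=median_differences,
    )
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Mutant-cycle runs


def load_activity_table(table: str | Path | pd.DataFrame) -> dict[str, ActivityRecord]:
    """Read a replicate activity table (columns: variant, replicate, kcat_per_km)."""
    if not isinstance(table, pd.DataFrame):
        path = Path(table)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        table = pd.read_csv(path, sep=sep)
    if "kcat_per_km" not in table.columns or "variant" not in table.columns:
        raise ConfigurationError("activity table needs 'variant' and 'kcat_per_km' columns")
    records = {}
    for variant, group in table.groupby("variant", sort=False):
        label = VariantLabel.parse(str(variant))
        records[str(label)] = ActivityRecord(
            variant=label, replicate_efficiencies=list(group["kcat_per_km"])
        )
    return records


def _lookup(records: dict[str, ActivityRecord], name: str) -> ActivityRecord:
    key = str(VariantLabel.parse(name))
    if key not in records:
        raise ConfigurationError(f"variant {key!r} not found in activity table")
    return records[key]


def run_cycles(
    table: str | Path | pd.DataFrame,
    cycles: list[tuple[str, str, str, str]],
    temperature_K: float = 298.15,
) -> dict:
    """Double-mutant-cycle report for each (wt, single1, single2, double) quadruple.

    For every cycle: the three fold changes over the background, the coupling
    coefficient Ω and ΔΔG_int, and Welch two-tailed p-values (log scale) with
    star annotations for each variant pair that shares an edge of the cycle.
    """
    records = load_activity_table(table)
    report: dict = {"temperature_K": temperature_K, "cycles": []}
    for wt_name, s1_name, s2_name, double_name in cycles:
        wt = _lookup(records, wt_name)
        s1 = _lookup(records, s1_name)
        s2 = _lookup(records, s2_name)
        double = _lookup(records, double_name)
        coupling = biochem.mutant_cycle(wt, s1, s2, double, temperature_K)
        folds = {
            f"{s1.variant}/{wt.variant}": biochem.fold_change(s1, wt).ratio,
            f"{s2.variant}/{wt.variant}": biochem.fold_change(s2, wt).ratio,
            f"{double.variant}/{wt.variant}": biochem.fold_change(double, wt).ratio,
            f"{double.variant}/{s1.variant}": biochem.fold_change(double, s1).ratio,
            f"{double.variant}/{s2.variant}": biochem.fold_change(double, s2).ratio,
        }
        edges = [(wt, s1), (wt, s2), (s1, double), (s2, double)]
        tests = {}
        for a, b in edges:
            key = f"{a.variant} vs {b.variant}"
            try:
                t, df, p = biochem.welch_t_test(
                    a.replicate_efficiencies, b.replicate_efficiencies
                )
                tests[key] = {"t": t, "df": df, "p": p, "stars": biochem.significance_stars(p)}
            except DomainMotionError:
                # too few replicates or degenerate variance: no test possible
                tests[key] = {"t": None, "df": None, "p": None, "stars": "n/a"}
        report["cycles"].append(
            {
                "variants": [str(v.variant) for v in (wt, s1, s2, double)],
                "fold_changes": folds,
                "omega": coupling.omega,
                "delta_delta_g_interaction_kcal_mol": coupling.delta_delta_g_interaction,
                "welch_tests": tests,
            }
        )
    return report
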