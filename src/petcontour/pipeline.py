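"""End-to-end orchestration: phantom -> registration -> thresholds -> report.

A run is fully described by a :class:`RunConfig` (usually loaded from
YAML) and a seed; rerunning with the same config and seed is bit-identical
for every CSV the run writes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio
from .model import ContouringValidation, SubjectData
from .phantom import Ellipsoid, PhantomConfig, default_cohort
from .registration import build_pair

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one validation run.

    Exactly one of ``phantom`` (synthetic cohort) or ``inputs`` (paths to
    real volume/sections/manifest) must be present.
    """

    phantom: dict | None = None
    inputs: dict | None = None
    percents: tuple[float, ...] | None = None
    liver_multiples: tuple[float, ...] | None = None
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.inputs is None):
            raise ValueError("exactly one of 'phantom' or 'inputs' must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "percents" in raw and raw["percents"] is not None:
            raw["percents"] = tuple(raw["percents"])
        if "liver_multiples" in raw and raw["liver_multiples"] is not None:
            raw["liver_multiples"] = tuple(raw["liver_multiples"])
        return cls(**raw)


_ELLIPSOID_FIELDS = ("necrosis_spec", "viable_cords")


def _coerce_phantom_kwargs(kw: dict) -> dict:
    """Allow ellipsoids in YAML as {center_mm, radii_mm} mappings."""
    kw = dict(kw)
    for name in _ELLIPSOID_FIELDS:
        if name in kw:
            kw[name] = tuple(
                e if isinstance(e, Ellipsoid)
                else Ellipsoid(tuple(e["center_mm"]), tuple(e["radii_mm"]))
                for e in kw[name]
            )
    if "liver" in kw and not isinstance(kw["liver"], Ellipsoid):
        kw["liver"] = Ellipsoid(
            tuple(kw["liver"]["center_mm"]), tuple(kw["liver"]["radii_mm"])
        )
    for name, val in kw.items():
        if isinstance(val, list):
            kw[name] = tuple(val)
    return kw


def _phantom_configs(spec: dict) -> list[PhantomConfig]:
    spec = dict(spec)
    explicit = spec.pop("configs", None)
    n = int(spec.pop("n_phantoms", 8))
    seed = int(spec.pop("seed", 0))
    overrides = spec.pop("overrides", {})
    if spec:
        raise ValueError(f"unknown phantom keys: {sorted(spec)}")
    if explicit is not None:
        return [PhantomConfig(**_coerce_phantom_kwargs(kw)) for kw in explicit]
    configs = default_cohort(n_phantoms=n, seed=seed)
    if overrides:
        overrides = _coerce_phantom_kwargs(overrides)
        configs = [dataclasses.replace(c, **overrides) for c in configs]
    return configs


def _subjects_from_inputs(inputs: dict) -> list[SubjectData]:
    volume = dataio.read_pet_volume(inputs["volume"])
    region = dataio.read_pet_volume(inputs["tumor_region"]).counts > 0.5
    manifest = dataio.read_manifest(inputs["manifest"])
    sections_dir = Path(inputs["sections_dir"])
    pairs = []
    for entry in manifest.entries:
        section = dataio.read_section(sections_dir / f"{entry.section_id}.png")
        pairs.append(build_pair(volume, section, entry))
    return [
        SubjectData(
            subject_id=str(inputs.get("subject_id", "subject1")),
            volume=volume,
            tumor_region=region,
            liver_center_mm=np.asarray(inputs["liver_center_mm"], dtype=float),
            pairs=pairs,
        )
    ]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute a full run and write its artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    kwargs = {}
    if config.percents is not None:
        kwargs["percents"] = config.percents
    if config.liver_multiples is not None:
        kwargs["liver_multiples"] = config.liver_multiples

    if config.phantom is not None:
        logger.info("stage phantom: generating synthetic cohort")
        model = ContouringValidation.from_phantoms(
            _phantom_configs(config.phantom), **kwargs
        )
    else:
        logger.info("stage input: reading volumes and sections")
        model = ContouringValidation(_subjects_from_inputs(config.inputs), **kwargs)

    logger.info("stage fit: thresholds, classification, aggregation")
    results = model.fit(n_boot=config.n_boot, seed=config.seed)

    files = {}

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = path.name

    write_csv("per_pair_metrics.csv", results.per_pair)
    write_csv("aggregate.csv", results.aggregate)
    roc_rows = [
        {"section_id": c.section_id, "fpr": p[0], "tpr": p[1], "auc": c.auc}
        for c in results.roc_curves
        if c.defined
        for p in c.points
    ]
    write_csv("roc_points.csv", pd.DataFrame(roc_rows))
    (out / "summary.txt").write_text(results.summary())
    files["summary.txt"] = "summary.txt"

    snapshot = dataclasses.asdict(config)
    (out / "config_snapshot.json").write_text(json.dumps(snapshot, indent=1, default=str))
    files["config_snapshot.json"] = "config_snapshot.json"
    (out / "outputs_manifest.json").write_text(json.dumps(sorted(files), indent=1))
    logger.info("run complete: %s", out)
    return out
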