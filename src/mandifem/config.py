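"""YAML (de)serialization of pipeline configuration.

A config file carries the phantom spec (including the parametric
mandible geometry and intensity model), the material table, the muscle
allocation table, the scenario load table and meshing options, so a run
is fully reproducible from one structured text file plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any, Dict

import yaml

from mandifem import analysis, model, phantom


def config_to_dict(config: analysis.PipelineConfig) -> Dict[str, Any]:
    spec = config.spec
    return {
        "phantom": {
            "bounding_box": list(spec.bounding_box),
            "voxel_size": spec.voxel_size,
            "noise_sigma": spec.noise_sigma,
            "blur_sigma": spec.blur_sigma,
            "seed": spec.seed,
            "intensity_means": {
                phantom.TISSUE_NAMES[c]: v for c, v in spec.intensity_means.items()
            },
            "geometry": dataclasses.asdict(spec.geometry),
        },
        "materials": {
            phantom.TISSUE_NAMES[c]: {"E_MPa": m.E, "nu": m.nu}
            for c, m in config.materials.materials.items()
        },
        "muscles": [dataclasses.asdict(m) for m in config.muscles],
        "scenarios": {
            f"{b.value}_{f.value}": {"Fz_N": fz, "Fx_N": fx}
            for (b, f), (fz, fx) in model.SCENARIO_LOADS.items()
        },
        "mesh": {"coarsen": config.coarsen},
        "segmentation": {
            "cleanup": config.cleanup,
            "use_ground_truth_labels": config.use_ground_truth_labels,
        },
        "regions": {
            name: [list(map(list, box)) for box in boxes]
            for name, boxes in model.region_boxes(
                spec.geometry, spec.bounding_box[1] / 2.0
            ).items()
        },
    }


_NAME_TO_CODE = {v: k for k, v in phantom.TISSUE_NAMES.items()}


def config_from_dict(d: Dict[str, Any]) -> analysis.PipelineConfig:
    ph = d.get("phantom", {})
    geom = phantom.MandibleGeometry(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in ph.get("geometry", {}).items()
        }
    )
    means = {
        _NAME_TO_CODE[name]: float(v)
        for name, v in ph.get(
            "intensity_means",
            {phantom.TISSUE_NAMES[c]: v for c, v in phantom.default_intensity_means().items()},
        ).items()
    }
    spec = phantom.PhantomSpec(
        bounding_box=tuple(ph.get("bounding_box", (15.0, 8.0, 6.0))),
        voxel_size=float(ph.get("voxel_size", 0.1)),
        geometry=geom,
        intensity_means=means,
        noise_sigma=float(ph.get("noise_sigma", 6.0)),
        blur_sigma=float(ph.get("blur_sigma", 0.05)),
        seed=int(ph.get("seed", 20170509)),
    )
    materials = model.TissueTable(
        {
            _NAME_TO_CODE[name]: model.Material(E=float(m["E_MPa"]), nu=float(m["nu"]))
            for name, m in d.get(
                "materials", config_to_dict(analysis.PipelineConfig())["materials"]
            ).items()
        }
    )
    muscles = [model.MuscleSpec(**m) for m in d["muscles"]] if "muscles" in d else model.default_muscles()
    seg = d.get("segmentation", {})
    return analysis.PipelineConfig(
        spec=spec,
        coarsen=int(d.get("mesh", {}).get("coarsen", 3)),
        use_ground_truth_labels=bool(seg.get("use_ground_truth_labels", False)),
        materials=materials,
        muscles=muscles,
        cleanup=bool(seg.get("cleanup", True)),
    )


def dump_config(config: analysis.PipelineConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(config), f, sort_keys=False)


def load_config(path: str) -> analysis.PipelineConfig:
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f))


def config_hash(config: analysis.PipelineConfig) -> str:
    """Stable short hash of the full configuration, logged with every run."""
    payload = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
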