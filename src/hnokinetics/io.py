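"""Config file loading (YAML/JSON) for conditions, rates and optics."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .params import ExperimentConditions, OpticsModel, RateConstantSet
from .reproduce import RunConfig


def _read_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping at the top level")
    return data


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML or JSON file.

    Recognised top-level keys: ``conditions``, ``rates``, ``optics``
    (mappings of the respective dataclass fields, SI units) and the scalar
    run options (``inhibition_targets``, ``replicates``, ``master_seed``,
    ``sampling``, ``output_dir``).  Missing keys fall back to defaults.
    """
    data = _read_mapping(path)
    kwargs = {}
    if "conditions" in data:
        kwargs["conditions"] = ExperimentConditions(**data["conditions"])
    if "rates" in data:
        kwargs["rates"] = RateConstantSet(**data["rates"])
    if "optics" in data:
        kwargs["optics"] = OpticsModel(**data["optics"])
    for key in ("replicates", "master_seed", "sampling", "output_dir"):
        if key in data:
            kwargs[key] = data[key]
    if "inhibition_targets" in data:
        kwargs["inhibition_targets"] = tuple(data["inhibition_targets"])
    return RunConfig(**kwargs)


def save_run_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
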