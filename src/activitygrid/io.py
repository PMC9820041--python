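"""Plain-text I/O: scenario CSVs, point GeoJSON, scenario config files."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import Scenario, ScenarioConfig


def write_points_geojson(points: pd.DataFrame, path,
                         properties=("category",)) -> None:
    """Write a point table (x, y + property columns) as a GeoJSON
    FeatureCollection."""
    feats = []
    for _, row in points.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
            "properties": {p: row[p] for p in properties if p in row},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_points_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for f in data["features"]:
        x, y = f["geometry"]["coordinates"][:2]
        rows.append({"x": x, "y": y, **f.get("properties", {})})
    return pd.DataFrame(rows)


def write_scenario(scenario: Scenario, out_dir) -> dict:
    """Write a scenario's tables as CSV (+ POI GeoJSON); returns the
    path inventory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pois": out / "pois.csv",
        "pois_geojson": out / "pois.geojson",
        "intensity": out / "intensity.csv",
        "attributes": out / "attributes.csv",
        "ground_truth": out / "ground_truth.csv",
        "config": out / "scenario_config.yaml",
    }
    scenario.pois.to_csv(paths["pois"], index=False)
    write_points_geojson(scenario.pois, paths["pois_geojson"])
    scenario.intensity.to_csv(paths["intensity"], index=False)
    t = scenario.truth
    t.attributes.to_csv(paths["attributes"])
    gt = pd.DataFrame({"label": t.labels, "sector_label": t.sector_labels})
    if t.change_rates is not None:
        gt = gt.join(t.change_rates.add_prefix("planted_"))
    gt.to_csv(paths["ground_truth"])
    write_scenario_config(scenario.config, paths["config"])
    return {k: str(v) for k, v in paths.items()}


def write_scenario_config(config: ScenarioConfig, path) -> None:
    """Scenario config as a flat YAML key-value file (the documented
    scenario schema: every ScenarioConfig field, YAML-typed)."""
    Path(path).write_text(yaml.safe_dump(
        {k: v for k, v in config.__dict__.items()}, sort_keys=True))


def read_scenario_config(path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return ScenarioConfig(**data)
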