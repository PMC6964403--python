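"""CSV dialects read and written by the pipeline.

All formats are plain headered CSV with an empty cell meaning missing:

* regions:   ``region_id,name,province,stratum,population,female_fraction,urban_fraction``
* survey:    ``region_id,age,sex,urbanicity,weight,asthma,copd,heart_disease,diabetes,less_than_hs``
* supplied:  ``scope,stratum,factor,urbanicity,value``
* pregnancy: ``stratum,live_births,fetal_losses,induced_abortions,female_population``
* surface:   ``cell_id,region_id,pollutant,year,concentration[,area_weight]``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthetic import SyntheticWorld, config_to_dict


def _read(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_regions(path) -> pd.DataFrame:
    return _read(
        path,
        ("region_id", "stratum", "population", "female_fraction", "urban_fraction"),
    )


def read_survey(path) -> pd.DataFrame:
    return _read(path, ("region_id", "age", "sex", "urbanicity", "weight"))


def read_supplied(path) -> pd.DataFrame:
    df = _read(path, ("scope", "stratum", "factor", "value"))
    if "urbanicity" not in df.columns:
        df["urbanicity"] = ""
    df["urbanicity"] = df["urbanicity"].fillna("")
    return df


def read_pregnancy(path) -> pd.DataFrame:
    return _read(
        path,
        ("stratum", "live_births", "fetal_losses", "induced_abortions",
         "female_population"),
    )


def read_surface(path) -> pd.DataFrame:
    return _read(path, ("cell_id", "region_id", "pollutant", "year", "concentration"))


def write_world(world: SyntheticWorld, out_dir) -> dict[str, Path]:
    """Write a generated world to a directory in the pipeline's dialects.

    ``truth.csv`` (true prevalences) and ``truth_totals.csv`` (true
    regional percents) support recovery tests; ``config.yaml`` records
    the generating configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("regions", world.regions),
        ("survey", world.survey),
        ("supplied_prevalence", world.supplied),
        ("pregnancy", world.pregnancy),
        ("surface", world.surface),
        ("truth", world.truth.prevalence),
        ("truth_totals", world.truth.regional_totals),
    ):
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    cfg = out / "config.yaml"
    cfg.write_text(yaml.safe_dump(config_to_dict(world.config), sort_keys=False))
    paths["config"] = cfg
    return paths
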