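"""Run configuration, age-group assignment and the subject manifest.

Defaults reproduce the canonical analysis choices: K = 4 microstates,
20 clustering restarts, 250 Hz working rate, the six-band table, and the
young-adult broadband templates as the re-ordering reference.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .bands import BAND_ORDER

__all__ = ["RunConfig", "AGE_GROUPS", "assign_age_group", "load_manifest"]

#: Age-group boundaries in years (closed integer bounds).
AGE_GROUPS: dict[str, tuple[int, int]] = {
    "YA": (18, 29),
    "EMA": (30, 44),
    "LMA": (45, 59),
    "YS": (60, 74),
    "EA": (75, 88),
}

GROUP_ORDER = tuple(AGE_GROUPS)


def assign_age_group(age: float) -> str:
    """Map an age in years onto the five cohort groups.

    Bounds are closed on integers and contiguous for fractional ages
    (29.5 still counts as YA).  Ages outside [18, 88] are an error.
    """
    if not 18 <= age <= 88:
        raise ValueError(f"age {age} outside the cohort range [18, 88]")
    for group, (lo, hi) in AGE_GROUPS.items():
        if age < hi + 1:
            return group
    return "EA"


@dataclass
class RunConfig:
    """All tunables of the end-to-end pipeline in one place."""

    bands: tuple[str, ...] = BAND_ORDER
    K: int = 4
    n_restarts: int = 20
    filter_order: int = 4
    scaling: str = "per-type-z"
    planar_rule: str = "rss"
    backfit_mode: str = "peak-interp"
    smooth_min_dur_s: float = 0.0  # 0 disables the minimum-duration smoother
    reference_group: str = "YA"
    reference_band: str = "overall"
    alpha: float = 0.05
    alpha_homog: float = 0.05
    bonferroni_m: int = 24  # one parameter across 4 states x 6 bands
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "results"
    max_skip_fraction: float = 0.10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["bands"] = list(d["bands"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


MANIFEST_COLUMNS = ("subject", "path", "age", "group", "sex", "handedness")


def load_manifest(path) -> pd.DataFrame:
    """Load a subject manifest CSV, deriving the age group where missing.

    Required columns: ``subject``, ``age``; optional: ``path``, ``group``,
    ``sex``, ``handedness``.  A missing/empty ``group`` is filled from
    ``age`` via :func:`assign_age_group`; a stated group must agree with
    the age bounds.
    """
    df = pd.read_csv(path)
    if "subject" not in df or "age" not in df:
        raise ValueError("manifest needs at least 'subject' and 'age' columns")
    if df["subject"].duplicated().any():
        raise ValueError("duplicate subject ids in manifest")
    for col in MANIFEST_COLUMNS:
        if col not in df:
            df[col] = pd.NA
    derived = df["age"].map(assign_age_group)
    stated = df["group"]
    df["group"] = stated.where(stated.notna() & (stated != ""), derived)
    bad = df.loc[df["group"] != derived, "subject"].tolist()
    if bad:
        raise ValueError(
            f"stated group disagrees with age-derived group for subjects: {bad}"
        )
    return df[list(MANIFEST_COLUMNS)]
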