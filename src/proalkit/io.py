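"""Pipeline configuration, table interchange and logging glue.

All tables are comma-separated UTF-8 text with a header row; configs and
manifests are YAML.  Every table written by the pipeline carries a comment
line with the config hash and master seed, so two runs with identical
config and seed produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("proalkit")
if not log.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


COHORT_COLUMNS = [
    "subject_id", "age", "gender", "vaq_preschool", "vaq_childhood",
    "vaq_adolescent", "vaq_preschool_t", "ras_total", "ras_emotion",
    "ras_social", "ras_situation", "stai_s", "stai_t",
    "omega2", "omega3", "zeta",
]

EVIDENCE_COLUMNS = ["subject_id", "model", "lme"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    n_subjects: int = 36
    models: tuple[str, ...] = ("hgf", "rw", "sk1")
    n_restarts: int = 8
    kappa: float = 1.0
    bms_alpha0: float = 1.0
    bms_tol: float = 1e-6
    bms_mc_samples: int = 100_000
    ebic_gamma: float = 0.25
    n_lambda: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls().__dict__
        unknown = set(raw) - set(known)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def write_table(df: pd.DataFrame, path, config_hash: str = "",
                seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path, required=None, schema=None) -> pd.DataFrame:
    """Read a delimited table; validate columns.

    ``required`` columns must all be present; with ``schema`` set, any
    column outside it is a SchemaError naming the column.
    """
    df = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
    if schema is not None:
        unknown = [c for c in df.columns if c not in schema]
        if unknown:
            raise SchemaError(f"{path}: unknown column {unknown[0]!r} "
                              f"(allowed: {list(schema)})")
    return df
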