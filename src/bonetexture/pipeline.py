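"""Orchestration of extract → associate → concordance with deterministic reports.

These functions sit directly behind the CLI subcommands but are equally
usable from Python.  Every report has a fixed column order and fixed float
formatting, so reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import io as bio
from .errors import BoneTextureError, JoinError, SchemaError
from .glcm import ATTRIBUTE_NAMES, GlcmConfig, extract
from .stats import InterRaterAgreement, TextureAssociation

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "run_extract",
    "run_associate",
    "run_concordance",
]


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration: GLCM settings plus analysis switches."""

    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    alpha: float = 0.05
    benjamini_hochberg: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a YAML config; keys mirror :class:`GlcmConfig` plus alpha/seed."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    glcm_keys = {f.name for f in fields(GlcmConfig)}
    glcm_raw = dict(raw.get("glcm", {}))
    unknown = set(glcm_raw) - glcm_keys
    if unknown:
        raise SchemaError(f"unknown glcm config key(s) {sorted(unknown)}")
    if "distances" in glcm_raw:
        glcm_raw["distances"] = tuple(int(d) for d in glcm_raw["distances"])
    if "directions" in glcm_raw:
        glcm_raw["directions"] = tuple(
            tuple(int(c) for c in d) for d in glcm_raw["directions"]
        )
    if str(glcm_raw.get("log_base", "")).lower() == "e":
        import math

        glcm_raw["log_base"] = math.e
    return RunConfig(
        glcm=GlcmConfig(**glcm_raw),
        alpha=float(raw.get("alpha", 0.05)),
        benjamini_hochberg=bool(raw.get("benjamini_hochberg", False)),
        seed=int(raw.get("seed", 0)),
    )


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the full configuration, for log provenance."""
    canon = yaml.safe_dump(
        {
            "glcm": {f.name: getattr(config.glcm, f.name) for f in fields(GlcmConfig)},
            "alpha": config.alpha,
            "benjamini_hochberg": config.benjamini_hochberg,
            "seed": config.seed,
        },
        sort_keys=True,
        default_flow_style=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def run_extract(
    manifest_path: str | os.PathLike,
    config: RunConfig | None = None,
    rater: str = "a",
    out_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Extract one feature vector per manifest subject.

    The manifest CSV carries ``id, volume`` and ``mask_a``/``mask_b``
    columns with paths relative to the manifest's directory.  A failure on
    any individual subject aborts the run with the subject id named.
    """
    config = config or RunConfig()
    mask_col = f"mask_{rater}"
    manifest = pd.read_csv(manifest_path, dtype={"id": str})
    for col in ("id", "volume", mask_col):
        if col not in manifest.columns:
            raise SchemaError(f"manifest is missing column {col!r}")
    base = Path(manifest_path).parent
    logger.info(
        "extract: %d subjects, rater %s, config %s",
        len(manifest),
        rater,
        config_hash(config),
    )
    rows = []
    for rec in manifest.itertuples(index=False):
        vol_path = base / getattr(rec, "volume")
        mask_path = base / getattr(rec, mask_col)
        try:
            volume = bio.read_volume(vol_path)
            mask = bio.read_mask(mask_path, volume)
            fv = extract(volume, mask, config.glcm)
        except (BoneTextureError, OSError) as exc:
            raise BoneTextureError(f"subject {rec.id}: {exc}") from exc
        logger.info("subject %s: %d non-empty matrices", rec.id, fv.n_matrices)
        rows.append({"id": rec.id, **fv.values, "n_matrices": fv.n_matrices})
    features = pd.DataFrame.from_records(rows)
    if out_path is not None:
        bio.write_features(features, out_path)
    return features


def run_associate(
    features: pd.DataFrame | str | os.PathLike,
    cohort: pd.DataFrame | str | os.PathLike,
    config: RunConfig | None = None,
    out_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Per-attribute association report (models 1 and 2), canonical order."""
    config = config or RunConfig()
    if not isinstance(features, pd.DataFrame):
        features = bio.read_features(features)
    if not isinstance(cohort, pd.DataFrame):
        cohort = bio.read_cohort(cohort)
    model = TextureAssociation(features, cohort)
    report = model.fit(alpha=config.alpha).to_frame(
        benjamini_hochberg=config.benjamini_hochberg
    )
    logger.info(
        "associate: n=%d subjects, %d/%d attributes significant at alpha=%g",
        model.nobs,
        int(report["significant"].sum()),
        len(report),
        config.alpha,
    )
    if out_path is not None:
        bio.write_report(report, out_path)
    return report


def run_concordance(
    features_a: pd.DataFrame | str | os.PathLike,
    features_b: pd.DataFrame | str | os.PathLike,
    config: RunConfig | None = None,
    out_path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Per-attribute interobserver concordance report (Lin CCC + CI + label)."""
    config = config or RunConfig()
    if not isinstance(features_a, pd.DataFrame):
        features_a = bio.read_features(features_a)
    if not isinstance(features_b, pd.DataFrame):
        features_b = bio.read_features(features_b)
    cols_a = [c for c in features_a.columns if c in ATTRIBUTE_NAMES]
    cols_b = [c for c in features_b.columns if c in ATTRIBUTE_NAMES]
    if set(cols_a) != set(cols_b):
        raise SchemaError(
            f"attribute sets differ between raters: "
            f"{sorted(set(cols_a) ^ set(cols_b))}"
        )
    model = InterRaterAgreement(features_a, features_b)
    report = model.fit(alpha=config.alpha).to_frame()
    logger.info(
        "concordance: n=%d subjects, %d/%d attributes 'almost perfect'",
        model.nobs,
        int((report["ccc"] >= 0.8).sum()),
        len(report),
    )
    if out_path is not None:
        bio.write_report(report, out_path)
    return report
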