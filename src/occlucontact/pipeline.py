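"""End-to-end study runs: meshes + particle scans + cohort table -> report.

``run_study`` joins per-subject OCA profiles (computed from aligned jaw
meshes or read from a cohort table) with X50 values (computed from particle
scans or read from the same table), applies the outlier rule, and writes
the correlation profile, best strategy, group comparison and descriptives,
all stamped with a hash of the run configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    CohortContentError,
    SubjectRecord,
    best_strategy,
    exclude_outliers,
    frame_to_records,
    pearson_profile,
    records_to_frame,
    strategy_column,
    summarize_groups,
)
from .digital_sieving import ChewingSample, ParticleImage, x50_from_image
from .jaw_alignment import orient_pair
from .mesh_io import read_landmarks, read_mesh
from .oca_core import (
    DEFAULT_OFFSETS_UM,
    DEFAULT_RASTER_PX_MM,
    DEFAULT_REFINE_MAX_EDGE_MM,
    OffsetProfile,
    compute_oca_profile,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a study run; serialized into every output."""

    offsets_um: tuple = DEFAULT_OFFSETS_UM
    refine_max_edge_mm: float = DEFAULT_REFINE_MAX_EDGE_MM
    raster_px_mm: float = DEFAULT_RASTER_PX_MM
    sieving_weighting: str = "volume_proxy"
    min_particle_area_mm2: float = 0.05
    outlier_k_sd: float = 2.0
    expected_sign: str = "negative"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offsets_um"] = list(self.offsets_um)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "offsets_um" in data:
            data["offsets_um"] = tuple(data["offsets_um"])
        return cls(**data)


class JoinError(ValueError):
    """Subject ids do not match across input sources."""


def _stamp(payload: dict, config: RunConfig) -> dict:
    payload["config_hash"] = config.config_hash()
    payload["package_version"] = __version__
    return payload


def run_study(config: RunConfig,
              cohort_csv: str | Path | None = None,
              mesh_pairs: dict | None = None,
              images: dict | None = None,
              groups: dict | None = None,
              out_dir: str | Path = "results") -> dict:
    """Run the full analysis and write the report bundle.

    Parameters
    ----------
    cohort_csv : ready-made cohort table (columns ``subject``, ``group``,
        ``x50_mm`` and one ``oca_{offset}um_{2d|3d}_mm2`` column per
        strategy). Mutually exclusive with per-subject raw inputs.
    mesh_pairs : subject id -> (mandible path, maxilla path, landmarks path).
    images : subject id -> (ParticleImage | path, ChewingSample | None).
        When both meshes and images are given, ids must match exactly.
    groups : subject id -> group label (required with raw inputs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}

    if cohort_csv is not None:
        if mesh_pairs or images:
            raise ValueError("pass either a cohort table or raw inputs, not both")
        frame = pd.read_csv(cohort_csv)
        expected = [strategy_column((t, proj)) for t in config.offsets_um
                    for proj in ("2d", "3d")]
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise CohortContentError(
                f"cohort table missing strategy columns: {missing}")
        records = frame_to_records(frame)
    else:
        records = _records_from_raw(config, mesh_pairs or {}, images or {},
                                    groups or {}, out)

    cohort_frame = records_to_frame(records)
    cohort_path = out / "cohort.csv"
    cohort_frame.to_csv(cohort_path, index=False)
    outputs["cohort"] = cohort_path

    # group comparison + descriptives use the full sample
    comparison = summarize_groups(records)
    comparison.descriptives.to_csv(out / "descriptives.csv", index=False)
    with open(out / "group_comparison.json", "w") as fh:
        json.dump(_stamp(comparison.as_dict(), config), fh, indent=2)
    outputs["group_comparison"] = out / "group_comparison.json"

    # correlation analysis on the outlier-trimmed sample
    kept, excluded = exclude_outliers(records, "x50", config.outlier_k_sd)
    profiles = []
    best = {}
    subsets = [("all", kept)]
    subsets += [(g, [r for r in kept if r.group == g])
                for g in sorted({r.group for r in kept})]
    for name, subset in subsets:
        if len(subset) < 3:
            log.warning("subset %s too small for correlation (n=%d)",
                        name, len(subset))
            continue
        prof = pearson_profile(subset, group=name)
        profiles.append(prof.to_frame())
        try:
            key, r = best_strategy(prof, expected_sign=config.expected_sign)
            best[name] = {"offset_um": key[0], "projection": key[1].upper(),
                          "r": r, "n": len(subset)}
        except CohortContentError:
            pass
    profile_frame = pd.concat(profiles, ignore_index=True)
    profile_frame.to_csv(out / "correlation_profile.csv", index=False)
    outputs["correlation_profile"] = out / "correlation_profile.csv"

    with open(out / "best_strategy.json", "w") as fh:
        json.dump(_stamp({"excluded_subjects": excluded, "best": best}, config),
                  fh, indent=2)
    outputs["best_strategy"] = out / "best_strategy.json"

    _plot_profile(profile_frame, out / "correlation_profile.png")
    with open(out / "run_config.json", "w") as fh:
        json.dump(_stamp(config.to_dict(), config), fh, indent=2)
    outputs["run_config"] = out / "run_config.json"
    outputs["records"] = records
    outputs["profile_frame"] = profile_frame
    outputs["best"] = best
    outputs["comparison"] = comparison
    outputs["excluded"] = excluded
    return outputs


def _records_from_raw(config: RunConfig, mesh_pairs: dict, images: dict,
                      groups: dict, out: Path) -> list:
    if not mesh_pairs or not images:
        raise ValueError("raw-input runs need both mesh pairs and images")
    orphans = set(mesh_pairs) ^ set(images)
    if orphans:
        raise JoinError(f"subject ids missing from one source: {sorted(orphans)}")
    missing_groups = set(mesh_pairs) - set(groups)
    if missing_groups:
        raise JoinError(f"no group label for subjects: {sorted(missing_groups)}")

    profile = OffsetProfile(config.offsets_um)
    oca_rows = []
    records = []
    for sid in sorted(mesh_pairs):
        mand_path, max_path, lm_path = mesh_pairs[sid]
        pair = orient_pair(read_mesh(mand_path), read_mesh(max_path),
                           read_landmarks(lm_path))
        oca = compute_oca_profile(pair, profile, config.refine_max_edge_mm,
                                  config.raster_px_mm, subject_id=sid)
        for t, a3, a2 in zip(oca.offsets_um, oca.areas_3d_mm2, oca.areas_2d_mm2):
            oca_rows.append({"subject": sid, "offset_um": t,
                             "projection": "3D", "area_mm2": a3})
            oca_rows.append({"subject": sid, "offset_um": t,
                             "projection": "2D", "area_mm2": a2})

        image, sample = images[sid]
        if not isinstance(image, ParticleImage):
            image = ParticleImage.from_file(image)
        fit, qc = x50_from_image(image, sample,
                                 min_area_mm2=config.min_particle_area_mm2,
                                 weighting=config.sieving_weighting)
        with open(out / f"x50_{sid}.json", "w") as fh:
            json.dump(_stamp({"subject": sid, "x50_mm": fit.x50, "b": fit.b,
                              "rmse": fit.rmse, **qc}, config), fh, indent=2)
        records.append(SubjectRecord(subject_id=sid, group=groups[sid],
                                     x50=fit.x50, oca=oca.as_dict()))
    pd.DataFrame(oca_rows).to_csv(out / "oca.csv", index=False)
    return records


def _plot_profile(profile_frame: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (group, proj), sub in profile_frame.groupby(["group", "projection"]):
        sub = sub.sort_values("offset_um")
        ax.plot(sub["offset_um"], sub["r"], marker="o", label=f"{group} {proj}")
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.axhline(-0.7, color="gray", lw=0.5, ls="--")
    ax.set_xscale("log")
    ax.set_xlabel("interocclusal distance (μm)")
    ax.set_ylabel("Pearson r (X50 vs. OCA)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
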