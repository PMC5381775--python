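"""End-to-end pipeline: train -> classify -> profile -> aggregate.

The pipeline is driven by a declarative :class:`PipelineConfig` (loadable
from YAML, overridable by keyword/flag), writes every artifact under one
output directory, and records a manifest with the config hash, seed and
library versions. Rerunning with identical config and inputs reproduces
byte-identical label maps and profile tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .classes import class_from_name
from .errors import ConfigurationError, InputError
from . import classifier, image_io, profiler

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of one end-to-end run.

    ``crops`` lists ``{path, class}`` training references; ``images``
    lists the confinement micrographs to classify and profile. Geometry
    is auto-detected per image unless ``center`` is given. Defaults match
    the reference setup: 25 um rings, three classes, red/blue/white
    overlay palette.
    """

    output_dir: str = "stainmap-out"
    crops: list[dict] = field(default_factory=list)
    images: list[str] = field(default_factory=list)
    pixel_size_um: float = 1.0
    diameter_um: float | None = None
    center: list[float] | None = None  # [x, y] px; None = auto-detect
    ring_um: float = profiler.DEFAULT_RING_THICKNESS_UM
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    min_blob_area: int = 0  # 0 = no spatial post-filter
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides win over file values."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class PipelineResult:
    """Paths of the artifacts a run produced, plus per-image failures."""

    output_dir: Path
    model_path: Path
    label_paths: list[Path]
    overlay_paths: list[Path]
    profile_paths: list[Path]
    aggregate_path: Path | None
    manifest_path: Path
    failed_images: list[str]

    @property
    def ok(self) -> bool:
        return not self.failed_images


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute train -> classify (per image) -> profile -> aggregate.

    Missing inputs fail fast with the offending path; a failure on one
    image is logged and the remaining images are still processed (the
    result records which images failed).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out / "run.log", config.log_level)

    crop_sources = [(c["path"], class_from_name(c["class"])) for c in config.crops]
    if not crop_sources:
        raise ConfigurationError("config lists no training crops")
    for path, _ in crop_sources:
        if not Path(path).exists():
            raise InputError(f"{path}: training crop not found")
    for path in config.images:
        if not Path(path).exists():
            raise InputError(f"{path}: input image not found")

    ts = classifier.load_training_crops(crop_sources)
    model = classifier.train(ts, C=config.svm_c, gamma=config.svm_gamma)
    model_path = out / "model.json"
    model.save(model_path)

    label_paths: list[Path] = []
    overlay_paths: list[Path] = []
    profile_paths: list[Path] = []
    profiles: list[profiler.RingProfile] = []
    failed: list[str] = []
    for img_path in config.images:
        try:
            stem = Path(img_path).stem
            image = image_io.load_rgb_image(img_path)
            labels = model.classify(image)
            if config.min_blob_area > 0:
                labels = classifier.filter_small_components(labels, config.min_blob_area)
            logger.info("%s: classified %d pixels", img_path, labels.size)

            lp = out / f"{stem}.labels.png"
            image_io.save_label_map(labels, lp)
            label_paths.append(lp)
            op = out / f"{stem}.overlay.png"
            image_io.save_rgb_image(classifier.render_overlay(labels), op)
            overlay_paths.append(op)

            if config.center is not None:
                if config.diameter_um is None:
                    raise ConfigurationError("explicit center requires diameter_um")
                geom = profiler.ConfinementGeometry(
                    config.center[0],
                    config.center[1],
                    config.diameter_um / 2.0 / config.pixel_size_um,
                    config.pixel_size_um,
                )
            else:
                geom = profiler.detect_confinement(
                    labels, config.pixel_size_um, config.diameter_um
                )
            rings = profiler.build_ring_index(geom, labels.shape, config.ring_um)
            profile = profiler.compute_ring_fractions(labels, rings)
            pp = out / f"{stem}.profile.csv"
            profile.to_frame().to_csv(pp, index=False)
            profile_paths.append(pp)
            profiles.append(profile)
        except Exception as exc:
            logger.error("%s: failed (%s)", img_path, exc)
            failed.append(str(img_path))

    aggregate_path: Path | None = None
    if profiles:
        aggregate = profiler.aggregate_profiles(profiles)
        aggregate_path = out / "aggregate_profile.csv"
        profiler.export_profile_table(aggregate, aggregate_path)

    manifest_path = out / "manifest.json"
    manifest = {
        "stainmap_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": _library_versions(),
        "artifacts": {
            "model": model_path.name,
            "label_maps": [p.name for p in label_paths],
            "overlays": [p.name for p in overlay_paths],
            "profiles": [p.name for p in profile_paths],
            "aggregate": aggregate_path.name if aggregate_path else None,
            "log": "run.log",
        },
        "failed_images": failed,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        output_dir=out,
        model_path=model_path,
        label_paths=label_paths,
        overlay_paths=overlay_paths,
        profile_paths=profile_paths,
        aggregate_path=aggregate_path,
        manifest_path=manifest_path,
        failed_images=failed,
    )


def _library_versions() -> dict:
    import numpy, sklearn, pandas  # noqa: E401

    return {"numpy": numpy.__version__, "scikit-learn": sklearn.__version__, "pandas": pandas.__version__}


def _setup_run_logging(log_path: Path, level: str) -> None:
    root = logging.getLogger("stainmap")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    # replace any stale file handler from a previous run in-process
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()
    fh = logging.FileHandler(log_path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.addHandler(fh)


__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]
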