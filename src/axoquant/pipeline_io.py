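"""Dataset layout, configuration, cohort simulation and end-to-end runs.

Cohort layout on disk::

    cohort/
      iop.csv
      manifest.yaml
      <animal>/SC/<eye>/section_##.tif(.json)      transport series
      <animal>/SC_LABEL/<eye>/<marker>.tif         immunolabel fields
      <animal>/SC_NUCLOC/<eye>/nfkb.tif            DAPI + NFKB fields
      <animal>/RETINA/<eye>/retina_##.tif          vertical sections

The eye pairing required by the ratio analyses is structural in the layout.
All outputs are deterministic given the config seed; the serialized config
and its hash are embedded in every report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    immunolabel_quant,
    morphometry,
    nuclear_localization,
    stats_reporting,
    synthetic_data,
    transport_mapping,
)
from .synthetic_data import Eye, SectionImage, SyntheticSpec, Tissue

GROUPS = ("VEHICLE", "HE20", "HE100")
_GROUP_PREFIX = {"VEHICLE": "V", "HE20": "L", "HE100": "H"}

# group-level effect sizes for the simulated cohort, calibrated to the
# reported directions and magnitudes (transport deficits, SC BDNF ratios,
# SC nuclear-NFKB ratios, retinal layer thicknesses, IOP elevation)
_GROUP_EFFECTS = {
    "VEHICLE": {
        "deficit_microbead": 0.43,
        "bdnf_ratio": 2.34,
        "nucloc_microbead": 0.355,
        "retina": (130.9, 16.8, 33.6),
    },
    "HE20": {
        "deficit_microbead": 0.28,
        "bdnf_ratio": 0.71,
        "nucloc_microbead": 0.625,
        "retina": (111.5, 14.1, 33.4),
    },
    "HE100": {
        "deficit_microbead": 0.15,
        "bdnf_ratio": 1.34,
        "nucloc_microbead": 0.495,
        "retina": (96.9, 13.2, 27.1),
    },
}
_DEFICIT_SALINE = 0.08
_BDNF_SALINE_FRACTION = 0.10
_NUCLOC_SALINE = 0.50


@dataclass
class RunConfig:
    """Thresholds, resolutions and seeds for one pipeline run; serialized
    verbatim (plus hash) into every report bundle."""

    transport_threshold: float = 0.70
    label_threshold: float = 0.5
    ctb_threshold: float = 0.5
    annulus_width: int = 3
    grid_resolution: int = 100
    n_profile_samples: int = 100
    reference: str = "percentile99"
    n_per_group: int = 6
    n_sections: int = 10
    image_size: tuple[int, int] = (64, 128)
    nuclei_image_size: tuple[int, int] = (128, 128)
    retina_image_size: tuple[int, int] = (160, 200)
    n_cells: int = 12
    rgc_count: int = 10
    n_dapi_distractors: int = 3
    n_iop_days: int = 28
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(d["image_size"])
        d["nuclei_image_size"] = list(d["nuclei_image_size"])
        d["retina_image_size"] = list(d["retina_image_size"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("image_size", "nuclei_image_size", "retina_image_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CohortManifest:
    """Animals, group assignment and per-animal file paths by modality."""

    root: Path
    animals: list[dict]  # {"id": ..., "group": ...}
    files: dict  # animal -> modality -> eye -> path(s)
    iop_csv: str
    exclusions: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        if not self.animals:
            raise ValueError("manifest has no animals")
        groups = {a["group"] for a in self.animals}
        unknown = groups - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        missing: list[str] = []

        def check(node) -> None:
            if isinstance(node, dict):
                for v in node.values():
                    check(v)
            elif isinstance(node, (list, tuple)):
                for v in node:
                    check(v)
            elif not (self.root / node).exists():
                missing.append(str(node))

        check(self.iop_csv)
        check(self.files)
        if missing:
            raise FileNotFoundError(
                f"manifest references missing files: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )

    def to_yaml(self, path: str | Path | None = None) -> Path:
        path = Path(path) if path else self.root / "manifest.yaml"
        payload = {
            "animals": self.animals,
            "files": self.files,
            "iop_csv": self.iop_csv,
            "exclusions": self.exclusions,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        d = yaml.safe_load(path.read_text())
        return cls(
            root=path.parent,
            animals=d["animals"],
            files=d["files"],
            iop_csv=d["iop_csv"],
            exclusions=d.get("exclusions", []),
        )

    def group_of(self, animal_id: str) -> str:
        for a in self.animals:
            if a["id"] == animal_id:
                return a["group"]
        raise KeyError(animal_id)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: RunConfig, out_dir: str | Path, effect_scale: float = 1.0
) -> CohortManifest:
    """Write a full three-group synthetic cohort with paper-calibrated,
    group-dependent effect sizes (scaled by ``effect_scale``; 0 zeroes all
    group differences)."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    cohort_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 999)))
    animals: list[dict] = []
    files: dict = {}
    iop_frames: list[pd.DataFrame] = []
    animal_seed = config.seed * 100_000

    def blend(base: float, value: float) -> float:
        return base + effect_scale * (value - base)

    for group in GROUPS:
        eff = _GROUP_EFFECTS[group]
        for i in range(config.n_per_group):
            animal_seed += 1
            animal = f"{_GROUP_PREFIX[group]}{i + 1}"
            animals.append({"id": animal, "group": group})
            files[animal] = {"transport": {}, "label": {}, "nucloc": {}, "retina": {}}
            adir = root / animal

            # transport series, one per eye
            for eye in (Eye.SALINE, Eye.MICROBEAD):
                target = (
                    _DEFICIT_SALINE
                    if eye is Eye.SALINE
                    else blend(_DEFICIT_SALINE, eff["deficit_microbead"])
                )
                f = float(np.clip(target + cohort_rng.normal(0, 0.02), 0.0, 0.95))
                spec = SyntheticSpec(
                    image_size=config.image_size,
                    n_sections=config.n_sections,
                    seed=animal_seed * 10 + (0 if eye is Eye.SALINE else 1),
                )
                sections, _ = synthetic_data.generate_sc_series(
                    spec, f, eye=eye, animal_id=animal
                )
                paths = []
                for s in sections:
                    p = adir / "SC" / eye.value / f"section_{s.section_index:02d}.tif"
                    synthetic_data.write_section(s, p)
                    paths.append(str(p.relative_to(root)))
                files[animal]["transport"][eye.value] = paths

            # immunolabel fields (one SC marker carries the ratio structure)
            sal_frac = _BDNF_SALINE_FRACTION
            mb_frac = float(
                np.clip(
                    sal_frac * blend(1.0, eff["bdnf_ratio"])
                    + cohort_rng.normal(0, 0.005),
                    0.0,
                    0.9,
                )
            )
            for eye, frac in ((Eye.SALINE, sal_frac), (Eye.MICROBEAD, mb_frac)):
                spec = SyntheticSpec(
                    image_size=config.image_size,
                    seed=animal_seed * 10 + (2 if eye is Eye.SALINE else 3),
                )
                img, _ = synthetic_data.generate_ihc_image(
                    spec, frac, eye=eye, animal_id=animal, marker="BDNF"
                )
                p = adir / "SC_LABEL" / eye.value / "BDNF.tif"
                synthetic_data.write_section(img, p)
                files[animal]["label"].setdefault("BDNF", {})[eye.value] = str(
                    p.relative_to(root)
                )

            # nuclear-localization fields
            for eye in (Eye.SALINE, Eye.MICROBEAD):
                nf = (
                    _NUCLOC_SALINE
                    if eye is Eye.SALINE
                    else blend(_NUCLOC_SALINE, eff["nucloc_microbead"])
                )
                nf = float(np.clip(nf + cohort_rng.normal(0, 0.01), 0.02, 0.98))
                spec = SyntheticSpec(
                    image_size=config.nuclei_image_size,
                    annulus_width=config.annulus_width,
                    seed=animal_seed * 10 + (4 if eye is Eye.SALINE else 5),
                )
                img, _ = synthetic_data.generate_nuclei_image(
                    spec, config.n_cells, nf, eye=eye, animal_id=animal
                )
                p = adir / "SC_NUCLOC" / eye.value / "nfkb.tif"
                synthetic_data.write_section(img, p)
                files[animal]["nucloc"][eye.value] = str(p.relative_to(root))

            # retinal sections
            rt, inl, onl = (blend(b, v) for b, v in zip((130.9, 16.8, 33.6), eff["retina"]))
            for eye in (Eye.SALINE, Eye.MICROBEAD):
                spec = SyntheticSpec(
                    image_size=config.retina_image_size,
                    pixel_size=1.0,
                    seed=animal_seed * 10 + (6 if eye is Eye.SALINE else 7),
                )
                img, _ = synthetic_data.generate_retina_section(
                    spec,
                    rt,
                    inl,
                    onl,
                    config.rgc_count,
                    n_dapi_distractors=config.n_dapi_distractors,
                    eye=eye,
                    animal_id=animal,
                )
                p = adir / "RETINA" / eye.value / "retina_00.tif"
                synthetic_data.write_section(img, p)
                files[animal]["retina"][eye.value] = [str(p.relative_to(root))]

            # tonometry
            spec = SyntheticSpec(seed=animal_seed * 10 + 8)
            iop = synthetic_data.generate_iop_series(
                spec,
                baseline_mmHg=20.12,
                elevation_fraction=0.327 * effect_scale,
                n_days=config.n_iop_days,
                animal_id=animal,
            )
            iop["group"] = group
            iop_frames.append(iop)

    iop_df = pd.concat(iop_frames, ignore_index=True)
    synthetic_data.write_iop_csv(iop_df, root / "iop.csv")
    manifest = CohortManifest(
        root=root, animals=animals, files=files, iop_csv="iop.csv"
    )
    manifest.to_yaml()
    manifest.validate()
    return manifest


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def _load(manifest: CohortManifest, relpath: str) -> SectionImage:
    return synthetic_data.read_section(manifest.root / relpath)


def run_pipeline(
    manifest: CohortManifest, config: RunConfig, out_dir: str | Path
) -> dict:
    """Execute every analysis stage over a cohort and write the report
    bundle (CSV tables, JSON report, serialized config).  Deterministic for
    a fixed manifest + config."""
    manifest.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "config_hash": config.config_hash}

    stage = "transport"
    try:
        rows = []
        for animal in sorted(manifest.files):
            group = manifest.group_of(animal)
            for eye, paths in sorted(manifest.files[animal]["transport"].items()):
                sections = [_load(manifest, p) for p in paths]
                res = transport_mapping.transport_from_sections(
                    sections,
                    n_samples=config.n_profile_samples,
                    grid_resolution=config.grid_resolution,
                    threshold=config.transport_threshold,
                    reference=config.reference,
                )
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "eye": eye,
                        "percent_intact": res.percent_intact,
                        "n_sections": res.n_sections,
                        "threshold": res.threshold,
                    }
                )
        transport_df = pd.DataFrame(rows).sort_values(["group", "animal_id", "eye"])
        _write_csv(transport_df, out / "transport.csv")
        report["transport_group_means"] = {
            f"{g}/{e}": round(float(sub["percent_intact"].mean()), 4)
            for (g, e), sub in transport_df.groupby(["group", "eye"], sort=True)
        }

        stage = "immunolabel_quant"
        label_rows, ratio_rows = [], []
        markers = sorted(
            {m for a in manifest.files.values() for m in a["label"].keys()}
        )
        for marker in markers:
            by_group: dict[str, list[tuple[str, float, float]]] = {}
            for animal in sorted(manifest.files):
                group = manifest.group_of(animal)
                eye_vals = {}
                for eye, relpath in sorted(manifest.files[animal]["label"][marker].items()):
                    img = _load(manifest, relpath)
                    roi = img.metadata.get("roi_mask", np.ones(img.shape, bool))
                    thr = img.metadata.get("label_threshold", config.label_threshold)
                    mask, thr = immunolabel_quant.threshold_positive_label(
                        img, marker, roi, method="fixed", threshold=thr
                    )
                    q = immunolabel_quant.percent_area_positive(
                        mask,
                        roi,
                        marker=marker,
                        tissue=img.tissue,
                        pixel_size=img.pixel_size,
                        threshold_used=thr,
                    )
                    eye_vals[eye] = q.percent_area
                    label_rows.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "marker": marker,
                            "tissue": img.tissue.value,
                            "eye": eye,
                            "percent_area": q.percent_area,
                            "threshold": thr,
                        }
                    )
                by_group.setdefault(group, []).append(
                    (animal, eye_vals["MICROBEAD"], eye_vals["SALINE"])
                )
            for group, vals in sorted(by_group.items()):
                _, summary = immunolabel_quant.microbead_saline_ratio(
                    vals, group=group, marker=marker
                )
                ratio_rows.append(
                    {
                        "marker": marker,
                        "group": group,
                        "n": summary.n,
                        "mean_ratio": summary.mean_ratio,
                        "sem": summary.sem,
                    }
                )
        _write_csv(pd.DataFrame(label_rows), out / "label.csv")
        label_summary = pd.DataFrame(ratio_rows)
        _write_csv(label_summary, out / "label_summary.csv")

        stage = "nuclear_localization"
        nuc_rows = []
        by_group = {}
        for animal in sorted(manifest.files):
            group = manifest.group_of(animal)
            eye_scores = {}
            for eye, relpath in sorted(manifest.files[animal]["nucloc"].items()):
                img = _load(manifest, relpath)
                labels = nuclear_localization.segment_nuclei(img.channel("DAPI"))
                res = nuclear_localization.nuclear_signal_fraction(
                    img.channel("NFKB"),
                    labels,
                    annulus_width=config.annulus_width,
                    pixel_size=img.pixel_size,
                )
                eye_scores[eye] = res.score
                nuc_rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "eye": eye,
                        "score": res.score,
                        "n_nuclei": res.n_nuclei,
                    }
                )
            by_group.setdefault(group, []).append(
                (animal, eye_scores["MICROBEAD"], eye_scores["SALINE"])
            )
        nuc_summary_rows = []
        for group, vals in sorted(by_group.items()):
            _, summary = nuclear_localization.nuclear_ratio_analysis(vals, group=group)
            nuc_summary_rows.append(
                {
                    "group": group,
                    "n": summary.n,
                    "mean_ratio": summary.mean_ratio,
                    "sem": summary.sem,
                }
            )
        _write_csv(pd.DataFrame(nuc_rows), out / "nucloc.csv")
        _write_csv(pd.DataFrame(nuc_summary_rows), out / "nucloc_summary.csv")

        stage = "morphometry"
        morpho_rows = []
        for animal in sorted(manifest.files):
            group = manifest.group_of(animal)
            for eye, paths in sorted(manifest.files[animal]["retina"].items()):
                results = []
                for relpath in paths:
                    img = _load(manifest, relpath)
                    bounds = img.metadata["boundaries_um"]
                    slope = float(np.tan(np.deg2rad(img.metadata.get("tilt_deg", 0.0))))
                    curves = {k: (float(v), slope) for k, v in bounds.items()}
                    width_um = img.shape[1] * img.pixel_size
                    thick = morphometry.measure_layer_thickness(
                        curves, x_extent_um=(0.0, width_um)
                    )
                    cnt = morphometry.count_rgc_density(
                        img.channel("CTB"),
                        img.channel("DAPI"),
                        img.metadata["gcl_mask"],
                        img.pixel_size,
                        ctb_threshold=config.ctb_threshold,
                    )
                    results.append(
                        dataclasses.replace(
                            thick, rgc_count=cnt.rgc_count, gcl_area_um2=cnt.gcl_area_um2
                        )
                    )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    avg = morphometry.average_per_animal(results)
                morpho_rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "eye": eye,
                        "retinal_thickness_um": avg.retinal_thickness_um,
                        "inl_thickness_um": avg.inl_thickness_um,
                        "onl_thickness_um": avg.onl_thickness_um,
                        "rgc_count": avg.rgc_count,
                        "rgc_density_per_um2": avg.rgc_density,
                        "n_images": len(paths),
                    }
                )
        _write_csv(pd.DataFrame(morpho_rows), out / "morphometry.csv")

        stage = "stats_reporting"
        iop_df = pd.read_csv(manifest.root / manifest.iop_csv)
        baseline = stats_reporting.baseline_iop_table(iop_df)
        _write_csv(baseline, out / "iop_baseline.csv")
        elevation = stats_reporting.iop_elevation_summary(iop_df)
        _write_csv(elevation, out / "iop_summary.csv")
        tests = {}
        for group, sub in transport_df.groupby("group", sort=True):
            sal = sub.loc[sub["eye"] == "SALINE", "percent_intact"]
            mb = sub.loc[sub["eye"] == "MICROBEAD", "percent_intact"]
            if len(sal) >= 3 and len(mb) >= 3:
                r = stats_reporting.compare_groups(sal, mb)
                tests[f"transport_{group}_saline_vs_microbead"] = {
                    "test": r.test_name.value,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "normality_pass": r.normality_pass,
                }
        report["tests"] = tests
        report["iop_elevation_percent"] = {
            row["group"]: row["mean_mmHg"]
            for _, row in elevation.iterrows()
            if row["eye"] == "ELEVATION_%"
        }
        report["label_ratio_means"] = {
            f"{r.marker}/{r.group}": round(float(r.mean_ratio), 4)
            for r in label_summary.itertuples()
        }
    except Exception as exc:  # noqa: BLE001 - stage-named abort is the contract
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8g", lineterminator="\n")
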