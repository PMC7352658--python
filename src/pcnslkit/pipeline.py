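"""End-to-end orchestration: synthetic inputs through clustering and survival.

A run is described by a validated :class:`RunConfig` (YAML-loadable).  One
global seed fans out to every stochastic stage through a documented
derivation (seed + CRC32 of the stage name, mod 2^31), stages execute in
dependency order, and each stage's JSON output is cached under a content
hash of its parameters so unchanged stages are reused on reruns.  The
final report only collects stage outputs — nothing is recomputed at
report time.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__, clustering, ihc, mri, spatial, survival
from . import synthetic

__all__ = [
    "RunConfig",
    "COHORT_SCHEMA",
    "stage_seed",
    "validate_cohort_schema",
    "run_pipeline",
]

STAGES = ("synth", "ihc", "spatial", "mri", "cluster", "survive")


class SynthParams(BaseModel):
    n_tiles: int = 4
    tile_size_px: int = 256
    cells_per_tile: int = 60
    positive_fraction: float = 0.2
    seg_shape: tuple[int, int, int] = (48, 48, 48)
    seg_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    multisector_patients: int = 26
    multisector_between_sd: float = 0.08
    multisector_within_sd: float = 0.10


class ClusterParams(BaseModel):
    k_female: int = 3
    k_male: int = 3
    min_cluster_size: int = 4


class SurvivalParams(BaseModel):
    screen_alpha: float = 0.1
    retention_alpha: float = 0.1
    min_leaf: int = 7
    screen_variables: list[str] = Field(
        default_factory=lambda: ["age", "ecog", "foxp3", "enhancing_cm3", "deep_pct"]
    )


class RunConfig(BaseModel):
    """Validated run configuration; ``from_yaml`` loads and validates a file."""

    seed: int = 0
    outdir: str = "pcnsl_run"
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    cohort_csv: str | None = None
    synth: SynthParams = Field(default_factory=SynthParams)
    cluster: ClusterParams = Field(default_factory=ClusterParams)
    survive: SurvivalParams = Field(default_factory=SurvivalParams)

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        unknown = set(v) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return v

    @field_validator("cohort_csv")
    @classmethod
    def _path_exists(cls, v):
        if v is not None and not Path(v).exists():
            raise ValueError(f"cohort_csv path does not exist: {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: (seed + CRC32(stage)) mod 2^31 — documented fan-out."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31)


#: Cohort column dictionary: (kind, (low, high)) domains; None = unbounded.
COHORT_SCHEMA: dict[str, tuple[str, tuple[float | None, float | None]]] = {
    "patient_id": ("string", (None, None)),
    "sex": ("category:female|male", (None, None)),
    "age": ("numeric", (18, 110)),
    "ecog": ("ordinal", (0, 4)),
    "n_foci": ("ordinal", (1, None)),
    "deep_pct": ("numeric", (0, 100)),
    "enhancing_cm3": ("numeric", (0, None)),
    "necrotic_cm3": ("numeric", (0, None)),
    "edema_cm3": ("numeric", (0, None)),
    "cd3": ("numeric", (0, 100)),
    "cd45ro": ("numeric", (0, 100)),
    "cd68": ("numeric", (0, 100)),
    "foxp3": ("numeric", (0, 100)),
    "immune_deficient": ("boolean", (None, None)),
    "chemo": ("boolean", (None, None)),
    "os_months": ("numeric", (0, None)),
    "event": ("boolean", (None, None)),
}


def validate_cohort_schema(source: str | Path | pd.DataFrame):
    """Check a cohort table against the column dictionary.

    Returns (table, errors): a typed DataFrame and a per-column list of
    error strings naming row and column — values are never silently
    coerced into range.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    errors: list[str] = []
    for col, (kind, (lo, hi)) in COHORT_SCHEMA.items():
        if col not in df.columns:
            errors.append(f"column {col!r}: missing")
            continue
        s = df[col]
        if kind.startswith("category:"):
            allowed = set(kind.split(":", 1)[1].split("|"))
            bad = df.index[~s.isna() & ~s.isin(allowed)]
            errors.extend(f"row {i} column {col!r}: value {df.loc[i, col]!r} "
                          f"not in {sorted(allowed)}" for i in bad)
        elif kind == "boolean":
            coerced = s.map({True: True, False: False, "True": True, "False": False,
                             1: True, 0: False})
            bad = df.index[~s.isna() & coerced.isna()]
            errors.extend(f"row {i} column {col!r}: value {df.loc[i, col]!r} "
                          "not boolean" for i in bad)
        elif kind in ("numeric", "ordinal"):
            num = pd.to_numeric(s, errors="coerce")
            bad = df.index[~s.isna() & num.isna()]
            errors.extend(f"row {i} column {col!r}: value {df.loc[i, col]!r} "
                          "not numeric" for i in bad)
            if lo is not None:
                out = df.index[num < lo]
                errors.extend(f"row {i} column {col!r}: value {num[i]:g} below {lo}"
                              for i in out)
            if hi is not None:
                out = df.index[num > hi]
                errors.extend(f"row {i} column {col!r}: value {num[i]:g} above {hi}"
                              for i in out)
            if kind == "ordinal":
                frac = num.dropna() % 1
                out = frac.index[frac != 0]
                errors.extend(f"row {i} column {col!r}: value {num[i]:g} not integral"
                              for i in out)
    return df, errors


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def _roundtrip(obj: Any) -> Any:
    """Serialize floats at 6 significant digits, recursively."""
    if isinstance(obj, dict):
        return {k: _roundtrip(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtrip(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage_hash(name: str, params: dict, upstream: str = "") -> str:
    payload = json.dumps({"stage": name, "params": params, "up": upstream}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _StageRunner:
    def __init__(self, outdir: Path):
        self.outdir = outdir

    def run(self, name: str, params: dict, upstream_hash: str, fn,
            force: bool = False) -> tuple[dict, str]:
        h = _stage_hash(name, params, upstream_hash)
        stage_dir = self.outdir / name
        cache = stage_dir / "output.json"
        marker = stage_dir / "hash.txt"
        if not force and cache.exists() and marker.exists() and marker.read_text().strip() == h:
            return json.loads(cache.read_text()), h
        stage_dir.mkdir(parents=True, exist_ok=True)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = fn()
        out = _roundtrip({"output": result, "warnings": sorted(str(w.message) for w in caught)})
        cache.write_text(json.dumps(out, indent=2, sort_keys=True))
        marker.write_text(h)
        return out, h


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order and write a report.

    Stage outputs are cached by content hash; a rerun with unchanged
    inputs reproduces the report body byte-identically.  A failing stage
    halts its dependents, which the report marks as skipped.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(outdir)
    report: dict[str, Any] = {
        "version": __version__,
        "config": _roundtrip(config.model_dump()),
        "stages": {},
        "warnings": [],
    }
    state: dict[str, Any] = {}
    failed: set[str] = set()
    deps = {"synth": (), "ihc": ("synth",), "spatial": ("synth",), "mri": ("synth",),
            "cluster": ("synth",), "survive": ("synth",)}
    hashes: dict[str, str] = {}

    def _synth():
        sp = config.synth
        seed = stage_seed(config.seed, "synth")
        if config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv)
            _, errors = validate_cohort_schema(cohort)
            if errors:
                raise ValueError("cohort validation failed: " + "; ".join(errors[:5]))
        else:
            cohort = synthetic.generate_cohort(synthetic.default_cohort_config(seed=seed))
        cohort.to_csv(outdir / "synth" / "cohort.csv", index=False)
        state["cohort"] = cohort
        n_pos = int(round(sp.positive_fraction * sp.cells_per_tile))
        tiles = []
        for i in range(sp.n_tiles):
            cfg = synthetic.TileConfig(
                width_px=sp.tile_size_px, height_px=sp.tile_size_px,
                n_negative=sp.cells_per_tile - n_pos, n_positive=n_pos,
                seed=stage_seed(seed, f"tile{i}"),
            )
            tiles.append(synthetic.generate_ihc_tile(cfg))
        state["tiles"] = tiles
        case, gt = synthetic.generate_segmentation_case(
            sp.seg_shape, sp.seg_spacing_mm,
            planted_foci=[
                ((sp.seg_shape[0] * 0.35,) * 3, 6.0, "enhancing"),
                ((sp.seg_shape[0] * 0.7,) * 3, 4.0, "enhancing"),
                ((sp.seg_shape[0] * 0.35,) * 3, 3.0, "necrosis"),
            ],
            seed=seed,
        )
        state["seg_case"], state["seg_gt"] = case, gt
        fractions = synthetic.generate_multisector_fractions(
            sp.multisector_patients, 2, sp.multisector_between_sd,
            sp.multisector_within_sd, seed=stage_seed(seed, "multisector"),
        )
        state["fractions"] = fractions
        return {
            "n_patients": len(cohort),
            "n_female": int((cohort["sex"] == "female").sum()),
            "n_male": int((cohort["sex"] == "male").sum()),
            "n_tiles": len(tiles),
            "planted_tile_fraction_pct": 100.0 * n_pos / sp.cells_per_tile,
            "seg_ground_truth": {"volumes_cm3": state["seg_gt"].volumes_cm3,
                                 "n_foci": state["seg_gt"].n_foci},
        }

    def _ihc():
        rows = []
        for i, (tile, gt) in enumerate(state["tiles"]):
            score, det_dab, det_hema = ihc.score_core(tile, marker="CD3")
            rows.append({"core": i, "n_dab": score.n_dab, "n_hema": score.n_hema,
                         "percent_positive": score.percent_positive,
                         "planted_percent": 100.0 * gt.planted_fraction})
        scores = pd.DataFrame(rows)
        scores.to_csv(outdir / "ihc" / "scores.csv", index=False)
        err = float((scores["percent_positive"] - scores["planted_percent"]).abs().mean())
        state["ihc_scores"] = scores
        return {"cores": rows, "mean_abs_error_pct_points": err}

    def _spatial():
        frac = state["fractions"]
        scores = frac.rename(columns={"fraction": "percent"}).assign(
            percent=lambda d: 100.0 * d["percent"], marker="CD3"
        )
        results = spatial.multisector_correlation(scores)
        analytic = spatial.gaussian_circle_mass()
        return {
            "multisector": [
                {"marker": r.marker, "r": r.r, "p": r.p, "n_pairs": r.n_pairs}
                for r in results
            ],
            "gaussian_circle_mass_analytic": analytic,
        }

    def _mri():
        case = state["seg_case"]
        feats = mri.extract_features(case)
        return {
            "enhancing_cm3": feats.enhancing_cm3,
            "necrotic_cm3": feats.necrotic_cm3,
            "edema_cm3": feats.edema_cm3,
            "n_foci": feats.n_foci,
            "pct_deep": feats.pct_deep,
            "pct_left": feats.pct_left,
        }

    def _cluster():
        cp = config.cluster
        res = clustering.sex_stratified_clustering(
            state["cohort"], k_female=cp.k_female, k_male=cp.k_male,
            min_cluster_size=cp.min_cluster_size, seed=stage_seed(config.seed, "cluster"),
        )
        out = {}
        for sex, r in res.items():
            r.assignments.to_csv(outdir / "cluster" / f"assignments_{sex}.csv")
            out[sex] = {
                "k": r.k,
                "sizes": {str(k): int(v) for k, v in r.sizes.items()},
                "excluded": r.excluded,
                "top_features": r.feature_tests.nsmallest(3, "p")["feature"].tolist(),
            }
        return out

    def _survive():
        sv = config.survive
        cohort = state["cohort"].dropna(subset=["os_months", "event"])
        sub = survival.filter_survival_cohort(cohort)
        out: dict[str, Any] = {"n_filtered": len(sub)}
        for sex in ("female", "male"):
            g = sub[sub["sex"] == sex]
            curve = survival.km_fit(g["os_months"], g["event"])
            out[f"median_os_{sex}"] = curve.median_os_months
        screen = survival.univariable_screen(
            sub.dropna(subset=sv.screen_variables), sv.screen_variables,
            alpha=sv.screen_alpha, min_leaf=sv.min_leaf,
        )
        screen.to_csv(outdir / "survive" / "screen.csv", index=False)
        selected = sorted(screen[screen["selected"]]["variable"].unique())
        out["screen_selected"] = selected
        if selected:
            cox = survival.cox_backward(
                sub.dropna(subset=selected), selected, retention_alpha=sv.retention_alpha
            )
            out["cox_terms"] = [
                {"variable": t.variable, "hr": t.hr, "ci": [t.ci95_low, t.ci95_high],
                 "p": t.p} for t in cox.terms
            ]
            out["cox_eliminated"] = cox.eliminated
        return out

    fns = {"synth": _synth, "ihc": _ihc, "spatial": _spatial, "mri": _mri,
           "cluster": _cluster, "survive": _survive}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if any(d in failed or d not in hashes for d in deps[stage]):
            report["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        params = config.model_dump().get(stage) or {}
        upstream = "|".join(hashes.get(d, "") for d in deps[stage])
        try:
            # synth always executes: downstream stages need its in-memory
            # arrays, and regeneration is deterministic under the seed
            wrapped, h = runner.run(stage, {"seed": config.seed, **params},
                                    upstream, fns[stage], force=(stage == "synth"))
            report["warnings"].extend(f"{stage}: {w}" for w in wrapped.get("warnings", []))
            hashes[stage] = h
            report["stages"][stage] = {"status": "ok", "output": wrapped["output"]}
        except Exception as exc:  # halt downstream, keep report
            failed.add(stage)
            report["stages"][stage] = {"status": f"failed: {exc}"}
    (outdir / "report.json").write_text(json.dumps(_roundtrip(report), indent=2, sort_keys=True))
    return report
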