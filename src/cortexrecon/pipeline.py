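"""End-to-end orchestration: configuration, QC filtering, the three
reconstruction stages, per-acquisition volume synthesis and QC reporting.

The pipeline is deterministic for a fixed seed and resumable: each stage's
outputs are cached on disk keyed by a hash of the configuration, so
deleting a late stage's cache re-runs only that stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    GMMask, ResolutionSchedule, SectionStack, SlabBounds, Volume3D,
    apply_transform_2d, load_manifest, load_section_image, load_volume,
    resample_volume, save_volume, dice,
)
from .init_align import chain_align_slab, rank_acquisitions
from .multires import MultiresState, rasterize_surfaces_to_gm, run_multires, \
    _resample_plane
from .segmentation import OtsuSegmenter, Segmenter, segment_stack
from .surface import (
    DepthSurfaceSet, SurfaceMesh, apply_upsample, generate_depth_surfaces,
    inflate_to_sphere, interpolate_sphere, project_to_volume,
    sample_sections_to_vertices, upsample_pattern, validate_external_sphere,
    vertex_voxel_coverage,
)
from .validation import intersection_dice, windowed_dice

log = logging.getLogger("cortexrecon")


@dataclass
class QcPolicy:
    """Automatic exclusion of sections missing too much cortex, plus a
    manual exclusion list."""

    max_missing_cortex_fraction: float = 0.25
    n_neighbors: int = 4
    min_area_fraction: float = 0.5   # of the slab median; below = tissue fragment
    manual_exclusions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_cortex_fraction <= 1:
            raise ValueError("max_missing_cortex_fraction must be in [0, 1]")
        if not 0 <= self.min_area_fraction <= 1:
            raise ValueError("min_area_fraction must be in [0, 1]")


@dataclass
class PipelineConfig:
    """Everything the reconstruction needs; serializable to/from YAML."""

    manifest: str = ""
    reference_volume: str = ""
    wm_mesh: str = ""
    pial_mesh: str = ""
    sphere_meshes: list[str] = field(default_factory=list)
    schedule: list[float] = field(default_factory=lambda: [4.0, 3.0, 2.0, 1.0, 0.5, 0.25])
    n_depth_surfaces: int = 10
    slab_bounds: dict = field(default_factory=dict)   # slab_id -> (posterior, anterior)
    seed: int = 0
    out_dir: str = "recon_out"
    qc: QcPolicy = field(default_factory=QcPolicy)

    def validate(self, check_files: bool = True) -> None:
        ResolutionSchedule(list(self.schedule))   # raises unless strictly decreasing
        if self.n_depth_surfaces < 2:
            raise ValueError("need at least 2 depth surfaces (WM and pial)")
        if check_files:
            for p in (self.manifest, self.reference_volume, self.wm_mesh,
                      self.pial_mesh, *self.sphere_meshes):
                if p and not Path(p).exists():
                    raise FileNotFoundError(p)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        qc = QcPolicy(**d.pop("qc", {}))
        cfg = cls(**d, qc=qc)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class ReconInput:
    """In-memory reconstruction input (real data loaded from disk, or a
    phantom handed over directly)."""

    stack: SectionStack
    images: dict
    ref_gm: Volume3D
    wm_mesh: SurfaceMesh
    pial_mesh: SurfaceMesh
    spheres: list[SurfaceMesh] | None = None
    bounds: dict[int, SlabBounds] = field(default_factory=dict)

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "ReconInput":
        import trimesh
        stack = load_manifest(cfg.manifest)
        root = Path(cfg.manifest).parent
        images = {}
        for r in stack.records:
            img = load_section_image(root / r.image_ref, r.pixel_size_um)
            images[(r.slab_id, r.sample_index)] = img.values
        ref = load_volume(cfg.reference_volume)
        ref = Volume3D((ref.values > 0.5).astype(float), spacing_mm=ref.spacing_mm,
                       origin=ref.origin, axis_map=ref.axis_map)

        def load_mesh(p):
            m = trimesh.load(str(p), process=False)
            return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))

        bounds = {int(k): SlabBounds(int(k), anterior_mm=float(v[1]),
                                     posterior_mm=float(v[0]))
                  for k, v in cfg.slab_bounds.items()}
        spheres = [load_mesh(p) for p in cfg.sphere_meshes] or None
        return cls(stack=stack, images=images, ref_gm=ref,
                   wm_mesh=load_mesh(cfg.wm_mesh), pial_mesh=load_mesh(cfg.pial_mesh),
                   spheres=spheres, bounds=bounds)


def qc_filter(stack: SectionStack, masks: dict, policy: QcPolicy) -> SectionStack:
    """Flag sections whose GM area falls short of their neighborhood.

    A section fails when its GM area is below (1 - max_missing_fraction)
    times the median area of its k nearest acquired neighbors in the same
    slab; manual exclusions are applied on top. Reasons are recorded on the
    records.
    """
    areas = {}
    for r in stack.records:
        key = (r.slab_id, r.sample_index)
        if key in masks:
            m = masks[key]
            areas[key] = float((m.values if isinstance(m, GMMask) else m).sum())
    slab_median = {
        s: float(np.median([a for k, a in areas.items() if k[0] == s]))
        for s in {k[0] for k in areas}
    }
    for r in stack.records:
        key = (r.slab_id, r.sample_index)
        if tuple(key) in {tuple(k) for k in policy.manual_exclusions}:
            r.qc_pass = False
            r.exclude_reason = "manual"
            log.info("qc: %s excluded (manual)", key)
            continue
        if key not in areas:
            continue
        if areas[key] < policy.min_area_fraction * slab_median.get(r.slab_id, 0.0):
            r.qc_pass = False
            r.exclude_reason = "fragment"
            log.info("qc: %s excluded (fragment: area %.0f below %.0f%% of slab "
                     "median)", key, areas[key], 100 * policy.min_area_fraction)
            continue
        nbrs = sorted(
            (k for k in areas if k[0] == r.slab_id and k != key),
            key=lambda k: abs(k[1] - r.sample_index))[:policy.n_neighbors]
        if not nbrs:
            continue
        med = float(np.median([areas[k] for k in nbrs]))
        if med > 0 and areas[key] < (1 - policy.max_missing_cortex_fraction) * med:
            r.qc_pass = False
            r.exclude_reason = "missing_cortex"
            log.info("qc: %s excluded (missing_cortex: %.0f < %.2f * %.0f)",
                     key, areas[key], 1 - policy.max_missing_cortex_fraction, med)
    if not any(r.qc_pass for r in stack.records):
        raise ValueError("all sections failed quality control")
    return stack


@dataclass
class ReconstructionResult:
    """Bundle of everything the pipeline produced."""

    config: PipelineConfig
    config_hash: str
    stack: SectionStack
    masks: dict
    ranking: object
    states: dict[int, MultiresState]
    volumes: dict[str, Volume3D]
    cortex_mask: Volume3D
    depth_surfaces: DepthSurfaceSet | None
    dice_table: pd.DataFrame
    vertex_coverage: float
    seg_log: list


def _cached(out_dir: Path | None, name: str, h: str, compute):
    if out_dir is None:
        return compute()
    out_dir.mkdir(parents=True, exist_ok=True)
    p = out_dir / f"{name}_{h}.pkl"
    if p.exists():
        log.info("stage %s: cached result found, skipping recompute", name)
        with open(p, "rb") as fh:
            return pickle.load(fh)
    res = compute()
    with open(p, "wb") as fh:
        pickle.dump(res, fh)
    return res


def run_reconstruction(
    inp: ReconInput,
    cfg: PipelineConfig,
    segmenter: Segmenter | None = None,
    precomputed_masks: dict | None = None,
    write_outputs: bool = False,
) -> ReconstructionResult:
    """Execute segmentation -> QC -> rigid chaining -> multi-resolution
    alignment -> surface interpolation, per acquisition.

    Deterministic for a fixed config seed. With ``write_outputs`` the
    per-acquisition volumes, Dice tables and config hash are written under
    ``cfg.out_dir``; stage caches make re-runs resumable.
    """
    cfg.validate(check_files=False)
    h = cfg.config_hash()
    out = Path(cfg.out_dir) if write_outputs else None
    cache_dir = out / "cache" if out else None
    stack = inp.stack
    images = {k: (v.values if hasattr(v, "values") else np.asarray(v, float))
              for k, v in inp.images.items()}
    pixel_mm = stack.records[0].pixel_size_um / 1000.0
    segmenter = segmenter or OtsuSegmenter()

    seg_log: list = []

    def stage_segment():
        if precomputed_masks is not None:
            masks = {k: (m if isinstance(m, GMMask) else GMMask(np.asarray(m, float)))
                     for k, m in precomputed_masks.items()}
        else:
            masks = segment_stack(stack, images, segmenter, log=seg_log)
        qc_filter(stack, masks, cfg.qc)
        return masks

    masks = _cached(cache_dir, "stage1_segment", h, stage_segment)

    def stage_rigid():
        ranking = rank_acquisitions(stack, masks, images)
        rigids = {}
        for slab in stack.slab_ids:
            sub = stack.for_slab(slab)
            for s, t in chain_align_slab(sub, masks, ranking).items():
                rigids[(slab, s)] = t
        return ranking, rigids

    ranking, rigids = _cached(cache_dir, "stage2_rigid", h, stage_rigid)

    schedule = ResolutionSchedule(list(cfg.schedule))

    def stage_multires():
        states = {}
        for slab in stack.slab_ids:
            sub = stack.for_slab(slab)
            bounds = inp.bounds.get(slab)
            if bounds is None and len(stack.slab_ids) > 1:
                raise ValueError(f"slab {slab}: bounds required for multi-slab input")
            states[slab] = run_multires(sub, masks, rigids, inp.ref_gm, bounds,
                                        schedule, pixel_mm, seed=cfg.seed)
        return states

    states = _cached(cache_dir, "stage3_multires", h, stage_multires)

    def stage_surface():
        res = schedule.final
        n_int = cfg.n_depth_surfaces - 2
        depth = generate_depth_surfaces(inp.wm_mesh, inp.pial_mesh, n_int)
        pat = upsample_pattern([inp.wm_mesh, inp.pial_mesh], res)
        depth_up = DepthSurfaceSet(
            meshes=[apply_upsample(m, pat) for m in depth.meshes],
            depths=depth.depths)
        if inp.spheres is not None:
            spheres = [validate_external_sphere(m, s)
                       for m, s in zip(depth.meshes, inp.spheres)]
            spheres_up = [apply_upsample(s, pat) for s in spheres]
        else:
            spheres_up = [apply_upsample(inflate_to_sphere(m), pat)
                          for m in depth.meshes]

        ref_fine = resample_volume(inp.ref_gm, res)
        cortex = rasterize_surfaces_to_gm(inp.wm_mesh, inp.pial_mesh, res,
                                          like=ref_fine)
        coverage = vertex_voxel_coverage(depth_up, cortex, cortex.values > 0.5)

        volumes = {}
        for acq in stack.acquisitions:
            fields = None
            for slab in stack.slab_ids:
                st = states[slab]
                slab_meshes = []
                for m in depth_up.meshes:
                    v = st.slab_transform.inverse_map_points(m.vertices) \
                        if st.slab_transform is not None else m.vertices
                    slab_meshes.append(SurfaceMesh(v, m.triangles, space_tag="slab"))
                sub = stack.for_slab(slab)
                fl = sample_sections_to_vertices(
                    sub, st.chains, DepthSurfaceSet(slab_meshes, depth_up.depths),
                    acq, images, pixel_mm, masks=masks)
                if fields is None:
                    fields = fl
                else:
                    for tot, new in zip(fields, fl):
                        take = new.known_mask & ~tot.known_mask
                        tot.values[take] = new.values[take]
                        tot.known_mask |= take
            complete = []
            for sph, fld in zip(spheres_up, fields):
                if fld.known_mask.sum() < 3:
                    log.warning("acquisition %s: too few samples on a depth "
                                "surface; filling with zeros", acq)
                    complete.append(type(fld)(np.zeros_like(fld.values),
                                              np.ones_like(fld.known_mask)))
                else:
                    complete.append(interpolate_sphere(sph, fld))
            volumes[acq] = project_to_volume(complete, depth_up, cortex,
                                             cortex.values > 0.5)
        return depth_up, cortex, coverage, volumes

    depth_up, cortex, coverage, volumes = _cached(cache_dir, "stage4_surface",
                                                  h, stage_surface)

    # ---- summary validation table ----------------------------------------
    rows = []
    res = schedule.final
    for slab, st in states.items():
        aligned = {}
        for r in stack.for_slab(slab).passing():
            key = (slab, r.sample_index)
            if key not in masks:
                continue
            arr = masks[key].values
            cur = apply_transform_2d(arr, st.chains[key], mode="linear",
                                     spacing_mm=(pixel_mm, pixel_mm))
            aligned[r.sample_index] = _resample_plane(
                np.clip(cur, 0, 1), pixel_mm, res) > 0.5
        inter = intersection_dice(aligned) if len(aligned) >= 2 else {}
        final_dice = st.dice_log[-1]["dice"] if st.dice_log else {}
        for s, mask_a in aligned.items():
            thick = stack.records[0].section_thickness_um / 1000.0
            jf = st.aligned_ref.world_to_index(s * thick)
            j = int(np.clip(np.floor(jf + 0.5 - 1e-9), 0,
                            st.aligned_ref.shape[1] - 1))
            refp = st.aligned_ref.plane(j) > 0.5
            shp = (min(mask_a.shape[0], refp.shape[0]),
                   min(mask_a.shape[1], refp.shape[1]))
            wd = np.nan
            if mask_a[:shp[0], :shp[1]].any():
                wd = windowed_dice(mask_a[:shp[0], :shp[1]], refp[:shp[0], :shp[1]])
            rows.append({
                "slab": slab, "sample": s,
                "dice_reference": final_dice.get(s, np.nan),
                "windowed_dice": wd,
                "dice_intersection": inter.get(s, np.nan),
            })
    table = pd.DataFrame(rows)

    result = ReconstructionResult(
        config=cfg, config_hash=h, stack=stack, masks=masks, ranking=ranking,
        states=states, volumes=volumes, cortex_mask=cortex,
        depth_surfaces=depth_up, dice_table=table,
        vertex_coverage=coverage, seg_log=seg_log,
    )
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config_hash.txt").write_text(h)
        table.to_csv(out / "dice_per_section.csv", index=False)
        for acq, v in volumes.items():
            save_volume(v, out / f"recon_{acq}.nii")
    return result


def qc_report(result: ReconstructionResult, out_dir: str | Path) -> list[Path]:
    """Write per-section overlay PNGs (aligned mask edges over the aligned
    reference plane) and a per-section Dice summary plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    pixel_mm = result.stack.records[0].pixel_size_um / 1000.0
    res = list(result.config.schedule)[-1]
    for slab, st in result.states.items():
        for r in result.stack.for_slab(slab).records:
            key = (slab, r.sample_index)
            if key not in result.masks:
                continue
            arr = result.masks[key].values
            cur = apply_transform_2d(arr, st.chains[key], mode="linear",
                                     spacing_mm=(pixel_mm, pixel_mm))
            cur = _resample_plane(np.clip(cur, 0, 1), pixel_mm, res) > 0.5
            thick = r.section_thickness_um / 1000.0
            jf = st.aligned_ref.world_to_index(r.sample_index * thick)
            j = int(np.clip(round(jf), 0, st.aligned_ref.shape[1] - 1))
            refp = st.aligned_ref.plane(j) > 0.5
            shp = (min(cur.shape[0], refp.shape[0]), min(cur.shape[1], refp.shape[1]))
            fig, ax = plt.subplots(figsize=(3, 3))
            ax.imshow(cur[:shp[0], :shp[1]], cmap="gray", interpolation="nearest")
            edge = refp[:shp[0], :shp[1]] ^ _erode(refp[:shp[0], :shp[1]])
            overlay = np.zeros(shp + (4,))
            overlay[edge] = (1.0, 0.4, 0.0, 1.0)
            ax.imshow(overlay, interpolation="nearest")
            marker = " [QC FAIL]" if not r.qc_pass else ""
            ax.set_title(f"slab {slab} sample {r.sample_index}{marker}", fontsize=7)
            ax.axis("off")
            p = out / f"overlay_s{slab}_{r.sample_index:04d}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written.append(p)
    fig, ax = plt.subplots(figsize=(6, 3))
    tb = result.dice_table
    for col, mk in (("dice_reference", "o"), ("dice_intersection", "s")):
        ax.plot(tb["sample"], tb[col], mk, ms=3, label=col)
    fails = [r.sample_index for r in result.stack.records if not r.qc_pass]
    for s in fails:
        ax.axvline(s, color="r", alpha=0.3, lw=0.8)
    ax.set_xlabel("sample index")
    ax.set_ylabel("Dice")
    ax.legend(fontsize=7)
    p = out / "dice_summary.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written


def _erode(m: np.ndarray) -> np.ndarray:
    from scipy import ndimage as ndi
    return ndi.binary_erosion(m)


__all__ = [
    "QcPolicy", "PipelineConfig", "ReconInput", "qc_filter",
    "ReconstructionResult", "run_reconstruction", "qc_report",
]
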