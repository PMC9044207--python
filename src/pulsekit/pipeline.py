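"""Orchestration: experiment configuration, video and dataset drivers.

An experiment is described by an INI-style configuration with the blocks

* ``[DATASET]`` — dataset name and paths;
* filter blocks (e.g. ``[BPFILTER]``) — named filter definitions with a
  ``params`` dict literal;
* ``[SIG]`` — extraction settings: window length ``winSize`` (s), stride,
  skin extractor, holistic vs patches, patch spec;
* ``[BVP]`` — ``methods = ['POS', 'GREEN']``, the list to compare;
* one block per method — implementation name, ``pre_filtering`` /
  ``post_filtering`` lists of filter-block names (``device_type`` is
  accepted and ignored; there is a single CPU implementation).

``run_on_video`` executes the full chain for one method on one video and
returns the windowed BPM estimate with its MAD uncertainty;
``run_on_dataset`` loops methods x videos, scores each prediction against
the contact-sensor reference with all five metrics and collects a
long-format results table.
"""

from __future__ import annotations

import ast
import configparser
import logging
import time
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from . import filters as flt
from .bvp import MethodSpec, available_methods, estimate_bvp, window_bvp
from .errors import ConfigError, ParameterError
from .extraction import (
    ChromaThresholdExtractor,
    GridLandmarkProvider,
    PatchSpec,
    TruthMaskExtractor,
    collect_skin_pixels,
    extract_holistic,
    extract_patches,
    window_signal,
)
from .metrics import compute_all
from .spectral import BPMSeries, estimate_bpm, reference_bpm
from .stats import ResultsTable
from .synthgen import GroundTruthPPG, SyntheticVideo, load_waveform_csv

__all__ = [
    "ExperimentConfig",
    "MethodConfig",
    "DatasetAdapter",
    "PairedListAdapter",
    "load_config",
    "save_config",
    "run_on_video",
    "run_on_dataset",
    "save_results",
    "load_results",
]

logger = logging.getLogger("pulsekit")

_RESERVED_BLOCKS = {"DATASET", "SIG", "BVP"}


@dataclass(frozen=True)
class MethodConfig:
    """Per-method experiment settings."""

    name: str
    implementation: str
    params: dict = field(default_factory=dict)
    pre_filtering: tuple[str, ...] = ()
    post_filtering: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment configuration with defaults filled in."""

    dataset_name: str = "synthetic"
    video_dir: str | None = None
    gt_dir: str | None = None
    window_s: float = 6.0
    stride_s: float = 1.0
    skin_extractor: str = "truth"  # 'truth' | 'chroma'
    approach: str = "holistic"  # 'holistic' | 'patches'
    n_patches: int = 16
    patch_side: int = 28
    fps: float | None = None
    methods: tuple[MethodConfig, ...] = ()
    filters: dict = field(default_factory=dict)  # name -> {'name':..., 'params':{...}}

    def method(self, name: str) -> MethodConfig:
        for m in self.methods:
            if m.name.upper() == name.upper():
                return m
        raise ConfigError(f"method {name!r} not configured")


_DEFAULT_FILTER_PARAMS = {"minHz": 0.65, "maxHz": 4.0, "fps": "adaptive", "order": 6}


def _parse_params(raw: str, block: str) -> dict:
    try:
        val = ast.literal_eval(raw)
    except (ValueError, SyntaxError) as e:
        raise ConfigError(f"malformed params in block [{block}]: {raw!r}") from e
    if not isinstance(val, dict):
        raise ConfigError(f"params in block [{block}] must be a dict literal")
    return val


def _parse_list(raw: str, block: str, key: str) -> list:
    try:
        val = ast.literal_eval(raw)
    except (ValueError, SyntaxError) as e:
        raise ConfigError(f"malformed {key} in block [{block}]: {raw!r}") from e
    if not isinstance(val, (list, tuple)):
        raise ConfigError(f"{key} in block [{block}] must be a list literal")
    return list(val)


def load_config(path) -> ExperimentConfig:
    """Parse and validate an INI experiment configuration.

    Unknown method implementations and references to undefined filter
    blocks raise :class:`ConfigError` naming the offending block; missing
    options fall back to the documented defaults (6 s windows, 1 s stride,
    0.65-4 Hz order-6 band, holistic extraction).
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise ConfigError(f"cannot read configuration file {path!r}")

    # filter blocks: any non-reserved section with a 'params' or name=*filter*
    filter_blocks: dict = {}
    method_sections = []
    bvp_methods: list[str] = []
    if cp.has_section("BVP"):
        bvp_methods = [str(m) for m in _parse_list(cp.get("BVP", "methods", fallback="[]"), "BVP", "methods")]
    if not bvp_methods:
        raise ConfigError("block [BVP] must define a nonempty methods list")

    method_names_upper = {m.upper() for m in bvp_methods}
    for section in cp.sections():
        if section in _RESERVED_BLOCKS:
            continue
        if section.upper() in method_names_upper:
            method_sections.append(section)
        else:
            params = dict(_DEFAULT_FILTER_PARAMS)
            if cp.has_option(section, "params"):
                params.update(_parse_params(cp.get(section, "params"), section))
            filter_blocks[section] = {
                "name": cp.get(section, "name", fallback="BPfilter"),
                "params": params,
            }

    methods = []
    for m in bvp_methods:
        section = next((s for s in method_sections if s.upper() == m.upper()), None)
        impl = m.upper()
        pre: tuple[str, ...] = ()
        post: tuple[str, ...] = ()
        params: dict = {}
        if section is not None:
            impl_raw = cp.get(section, "name", fallback=m)
            # accept pyVHR-style 'cpu_POS' names; the device prefix is ignored
            impl = impl_raw.split("_")[-1].upper()
            pre = tuple(_parse_list(cp.get(section, "pre_filtering", fallback="[]"), section, "pre_filtering"))
            post = tuple(_parse_list(cp.get(section, "post_filtering", fallback="[]"), section, "post_filtering"))
            if cp.has_option(section, "params"):
                params = _parse_params(cp.get(section, "params"), section)
        if impl not in {x.upper() for x in available_methods()}:
            raise ConfigError(
                f"block [{section or m}] names unknown method {impl!r}; "
                f"available: {available_methods()}"
            )
        for f in (*pre, *post):
            if f not in filter_blocks:
                raise ConfigError(
                    f"block [{section or m}] references undefined filter block [{f}]"
                )
        methods.append(
            MethodConfig(name=m, implementation=impl, params=params,
                         pre_filtering=pre, post_filtering=post)
        )

    sig = cp["SIG"] if cp.has_section("SIG") else {}
    ds = cp["DATASET"] if cp.has_section("DATASET") else {}
    fps_raw = sig.get("fps", "adaptive") if hasattr(sig, "get") else "adaptive"
    fps = None if str(fps_raw) == "adaptive" else float(fps_raw)
    cfg = ExperimentConfig(
        dataset_name=ds.get("dataset", "synthetic") if hasattr(ds, "get") else "synthetic",
        video_dir=ds.get("videodataDIR", None) if hasattr(ds, "get") else None,
        gt_dir=ds.get("BVPdataDIR", None) if hasattr(ds, "get") else None,
        window_s=float(sig.get("winSize", 6.0)),
        stride_s=float(sig.get("stride", 1.0)),
        skin_extractor=str(sig.get("skin_extractor", "truth")),
        approach=str(sig.get("approach", "holistic")),
        n_patches=int(sig.get("patches", 16)),
        patch_side=int(float(sig.get("patch_side", 28))),
        fps=fps,
        methods=tuple(methods),
        filters=filter_blocks,
    )
    if cfg.approach not in ("holistic", "patches"):
        raise ConfigError(f"[SIG] approach must be holistic or patches, got {cfg.approach!r}")
    if cfg.stride_s >= cfg.window_s:
        raise ConfigError("[SIG] stride must be smaller than winSize")
    return cfg


def save_config(cfg: ExperimentConfig, path) -> None:
    """Write a configuration back to INI (round-trips through load_config)."""
    cp = configparser.ConfigParser()
    cp["DATASET"] = {
        "dataset": cfg.dataset_name,
        "videodataDIR": str(cfg.video_dir or ""),
        "BVPdataDIR": str(cfg.gt_dir or ""),
    }
    cp["SIG"] = {
        "winSize": str(cfg.window_s),
        "stride": str(cfg.stride_s),
        "skin_extractor": cfg.skin_extractor,
        "approach": cfg.approach,
        "patches": str(cfg.n_patches),
        "patch_side": str(cfg.patch_side),
        "fps": "adaptive" if cfg.fps is None else str(cfg.fps),
    }
    for fname, fdef in cfg.filters.items():
        cp[fname] = {"name": fdef["name"], "params": repr(fdef["params"])}
    cp["BVP"] = {"methods": repr([m.name for m in cfg.methods])}
    for m in cfg.methods:
        cp[m.name] = {
            "name": m.implementation,
            "device_type": "cpu",
            "pre_filtering": repr(list(m.pre_filtering)),
            "post_filtering": repr(list(m.post_filtering)),
        }
        if m.params:
            cp[m.name]["params"] = repr(m.params)
    with open(path, "w") as f:
        cp.write(f)


# --------------------------------------------------------------------------
# Dataset adapter contract
# --------------------------------------------------------------------------


@runtime_checkable
class DatasetAdapter(Protocol):
    """Pairing of videos with their ground-truth waveforms, by index."""

    def load_filenames(self) -> tuple[list, list]: ...

    def read_sigfile(self, path) -> GroundTruthPPG: ...


class PairedListAdapter:
    """Adapter over parallel lists of videos and ground-truth sources.

    Entries may be file paths (CSV waveforms, PNG-sequence directories or
    containers) or in-memory objects (SyntheticVideo, GroundTruthPPG),
    which makes the adapter equally usable for real folders and for fully
    synthetic experiments.
    """

    def __init__(self, videos: list, ground_truths: list, gt_sample_rate: float | None = None):
        if len(videos) != len(ground_truths):
            raise ParameterError("video and ground-truth lists must pair by index")
        self.videos = list(videos)
        self.ground_truths = list(ground_truths)
        self.gt_sample_rate = gt_sample_rate

    def load_filenames(self) -> tuple[list, list]:
        return self.videos, self.ground_truths

    def read_sigfile(self, src) -> GroundTruthPPG:
        if isinstance(src, GroundTruthPPG):
            return src
        return load_waveform_csv(src, sample_rate=self.gt_sample_rate)


# --------------------------------------------------------------------------
# Drivers
# --------------------------------------------------------------------------


def _build_extractor(video, cfg: ExperimentConfig):
    if cfg.skin_extractor == "truth":
        if not isinstance(video, SyntheticVideo):
            raise ConfigError(
                "the 'truth' skin extractor only applies to synthetic videos; "
                "use 'chroma' or plug in a custom extractor"
            )
        return TruthMaskExtractor.for_video(video)
    if cfg.skin_extractor == "chroma":
        return ChromaThresholdExtractor()
    raise ConfigError(f"unknown skin extractor {cfg.skin_extractor!r}")


def _apply_filter_chain(windows, chain: tuple[str, ...], cfg: ExperimentConfig, fps: float):
    for fname in chain:
        fdef = cfg.filters[fname]
        params = dict(fdef["params"])
        if params.get("fps") == "adaptive":
            params["fps"] = fps
        name = str(fdef["name"]).lower()
        if "bp" in name or "butter" in name or "band" in name:
            fp = flt.FilterParams(
                minHz=float(params.get("minHz", 0.65)),
                maxHz=float(params.get("maxHz", 4.0)),
                fps=float(params.get("fps", fps)),
                order=int(params.get("order", 6)),
            )
            windows = flt.apply_filter(windows, flt.bandpass, params=fp)
        elif "detrend" in name:
            windows = flt.apply_filter(
                windows, flt.detrend,
                method=params.get("method", "linear"),
                lam=float(params.get("lambda", 300.0)),
            )
        elif "zero" in name or "mean" in name:
            windows = flt.apply_filter(windows, flt.zero_mean)
        else:
            raise ConfigError(f"filter block [{fname}] has unknown filter {fdef['name']!r}")
    return windows


def process_video(
    video,
    cfg: ExperimentConfig,
    method: str | MethodConfig,
    fps: float | None = None,
    extractor=None,
    landmark_provider=None,
):
    """Full chain for one (video, method): returns (BPMSeries, BVPWindows).

    Stages: skin extraction -> trace (holistic or patches) -> windowing ->
    pre-filter -> pulse estimation -> post-filter -> Welch BPM with MAD
    uncertainty.  Per-stage durations are logged at debug level.
    """
    import os

    if isinstance(video, (str, os.PathLike)) and not os.path.exists(video):
        raise IOError(f"video not found or unreadable: {video!r}")
    mcfg = cfg.method(method) if isinstance(method, str) else method
    mspec = MethodSpec(name=mcfg.implementation, params=dict(mcfg.params))
    if extractor is None and not isinstance(video, SyntheticVideo) and cfg.skin_extractor == "truth":
        extractor = ChromaThresholdExtractor()
    extractor = extractor or _build_extractor(video, cfg)
    fps = fps or cfg.fps

    t0 = time.perf_counter()
    try:
        if mspec.input_kind == "pixels":
            pix = collect_skin_pixels(video, extractor, fps=fps)
            fps_eff = pix.fps
            logger.debug("extraction: %.3fs", time.perf_counter() - t0)
            bvp_full = estimate_bvp(pix, mspec)
            series = bvp_full.windows[0]
            bvp = window_bvp(series[0], fps_eff, cfg.window_s, cfg.stride_s)
            bvp = _apply_filter_chain(bvp, mcfg.post_filtering, cfg, fps_eff)
        else:
            if cfg.approach == "patches":
                if landmark_provider is None:
                    if isinstance(video, SyntheticVideo):
                        landmark_provider = GridLandmarkProvider(video.skin_box)
                    else:
                        raise ConfigError(
                            "patch extraction needs a landmark provider for real videos"
                        )
                n = cfg.n_patches
                pspec = PatchSpec(landmark_indices=tuple(range(n)), side=cfg.patch_side)
                trace = extract_patches(video, extractor, pspec, landmark_provider, fps=fps)
            else:
                trace = extract_holistic(video, extractor, fps=fps)
            fps_eff = trace.fps
            logger.debug("extraction: %.3fs", time.perf_counter() - t0)
            t0 = time.perf_counter()
            windowed = window_signal(trace, cfg.window_s, cfg.stride_s)
            windowed = _apply_filter_chain(windowed, mcfg.pre_filtering, cfg, fps_eff)
            logger.debug("windowing+prefilter: %.3fs", time.perf_counter() - t0)
            t0 = time.perf_counter()
            bvp = estimate_bvp(windowed, mspec)
            bvp = _apply_filter_chain(bvp, mcfg.post_filtering, cfg, fps_eff)
            logger.debug("bvp+postfilter: %.3fs", time.perf_counter() - t0)
        t0 = time.perf_counter()
        bpm = estimate_bpm(bvp)
        logger.debug("bpm: %.3fs", time.perf_counter() - t0)
    except Exception as e:
        raise type(e)(f"[method {mcfg.name}] {e}") from e
    return bpm, bvp


def run_on_video(
    video,
    cfg: ExperimentConfig | None = None,
    method: str | None = None,
    fps: float | None = None,
    extractor=None,
    landmark_provider=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the pipeline on one video; returns (timestamps, bpm, uncertainty).

    With no configuration, a default holistic run with the POS method and
    6 s / 1 s windowing is used (truth-mask extraction for synthetic
    videos).  The uncertainty is the per-window MAD of the patch BPM
    predictions (identically 0 for holistic runs).
    """
    if cfg is None:
        cfg = ExperimentConfig(
            methods=(MethodConfig(name="POS", implementation="POS"),)
        )
    mname = method or cfg.methods[0].name
    bpm, _ = process_video(
        video, cfg, mname, fps=fps, extractor=extractor,
        landmark_provider=landmark_provider,
    )
    return bpm.timestamps, bpm.bpm, bpm.mad


def run_on_dataset(cfg: ExperimentConfig, adapter: DatasetAdapter) -> ResultsTable:
    """Evaluate every configured method on every (video, truth) pair.

    Per pair and method: predict the windowed BPM, derive the reference BPM
    from the contact waveform with the same windowing, compute MAE, RMSE,
    PCC, CCC and SNR, and append the rows.  Per-video failures are logged
    and recorded as missing rather than aborting the run.
    """
    videos, gts = adapter.load_filenames()
    if not videos:
        raise ParameterError("dataset adapter returned no videos")
    table = ResultsTable()
    for idx, (video, gt_src) in enumerate(zip(videos, gts)):
        vid_id = f"video_{idx:03d}"
        try:
            gt = adapter.read_sigfile(gt_src)
            ref = reference_bpm(gt, cfg.window_s, cfg.stride_s)
        except Exception:
            logger.exception("ground truth failed for %s; skipping", vid_id)
            continue
        for mcfg in cfg.methods:
            try:
                bpm, bvp = process_video(video, cfg, mcfg)
                K = min(len(bpm.bpm), len(ref.bpm))
                res = compute_all(
                    bpm.bpm[:K], ref.bpm[:K],
                    bvp=type(bvp)(windows=bvp.windows[:K], fps=bvp.fps,
                                  timestamps=bvp.timestamps[:K]),
                )
            except Exception:
                logger.exception("method %s failed on %s", mcfg.name, vid_id)
                continue
            for metric, value in res.items():
                table.add(cfg.dataset_name, vid_id, mcfg.name, metric, value)
    return table


def save_results(table: ResultsTable, path) -> None:
    table.save(path)


def load_results(path) -> ResultsTable:
    return ResultsTable.load(path)
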