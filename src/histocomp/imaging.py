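"""Automated 3D image analysis of nuclear-labelled embryo stacks.

The quantification chain is:

1. :func:`segment_nuclei` — per-nucleus segmentation by a global seed
   threshold followed by per-component iterative local (Otsu) re-thresholding,
   which compensates for intensity differences across the sample;
2. :func:`cytoplasm_shell` — a two-step dilation shell around each nucleus
   (the once-extended shell and all nuclei are removed from the twice-extended
   shell), sampling local cytoplasm;
3. :func:`nc_ratio` — background-corrected nuclear-over-cytoplasmic mean
   intensity ratio R per nucleus;
4. :func:`filter_interphase` — only nuclei with R strictly greater than 2
   enter downstream statistics (removes mitotic or degraded nuclei);
5. :func:`segment_cap` — animal-cap segmentation from a single global
   threshold derived from the maximum-intensity z-projection;
6. :func:`track_nuclei` / :func:`volume_fraction` — centroid-distance
   tracking across frames and the nuclear volume fraction v computed from
   per-track maximal-extension volumes;
7. :func:`count_cells` — cell counting as accepted-segment counting.

All geometric quantities are in physical µm units; voxel anisotropy is
honoured throughout (distance transforms use the physical voxel size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NucleusSegment:
    """One segmented nucleus and its intensity statistics."""

    label: int
    slices: tuple[slice, slice, slice]
    mask: np.ndarray  # boolean, within ``slices``
    centroid: tuple[float, float, float]  # µm, ZYX
    volume: float  # µm³
    voxel_count: int
    frame: int = 0
    mean_nuclear_intensity: float = float("nan")
    mean_shell_intensity: float = float("nan")
    nc_ratio: float = float("nan")
    touches_border: bool = False
    valid_ratio: bool = True

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slices][self.mask] = True
        return out


@dataclass
class CapSegmentation:
    """3D animal-cap mask with its volume and the threshold used."""

    mask: np.ndarray
    cap_volume: float
    threshold: float


@dataclass
class Track:
    """One nucleus followed across frames."""

    track_id: int
    items: list[tuple[int, int]] = field(default_factory=list)  # (frame, label)
    volumes: list[float] = field(default_factory=list)

    @property
    def max_extension_volume(self) -> float:
        return max(self.volumes)

    def add(self, frame: int, label: int, volume: float) -> None:
        if self.items and frame <= self.items[-1][0]:
            raise ValueError("frames must be strictly increasing within a track")
        self.items.append((frame, label))
        self.volumes.append(volume)


def _safe_otsu(values: np.ndarray) -> float | None:
    """Otsu threshold of a 1D sample, or None if the sample is constant.

    For images with only a few discrete levels the exact level histogram is
    used: with binned data the returned threshold can be the centre of a bin
    holding one (or, for uneven level spacing, two) of the levels, putting
    voxels on the wrong side of a strict ``>`` comparison. With the exact
    histogram the threshold is the top level of the lower Otsu class, so
    ``values > threshold`` reproduces the Otsu classes exactly.
    """
    values = np.asarray(values)
    if values.size == 0 or np.all(values == values.flat[0]):
        return None
    unique, counts = np.unique(values, return_counts=True)
    if len(unique) == 1:
        return None
    if len(unique) <= 256:
        return float(threshold_otsu(hist=(counts, unique)))
    return float(threshold_otsu(values, nbins=256))


def _seed_threshold(stack: np.ndarray, cap_mask: np.ndarray | None):
    """Global nuclear seed threshold.

    A single Otsu pass on a background/cytoplasm/nuclei image separates
    background from embryo, not cytoplasm from nuclei, so the seed is found
    in two stages: Otsu for the embryo foreground, then Otsu within the
    foreground. On binary-contrast stacks (nuclei vs flat rest) the second
    stage degenerates and the foreground itself is the nuclear mask.
    """
    if cap_mask is None:
        t0 = _safe_otsu(stack.ravel())
        if t0 is None:
            return None, None
        fg = stack > t0
    else:
        fg = cap_mask
    vals = stack[fg]
    t1 = _safe_otsu(vals)
    if t1 is None:
        # flat foreground: the foreground is already the nuclear mask
        return fg, fg
    return (stack > t1) & fg, fg


def _component_segment(
    label_img: np.ndarray, label: int, sl, voxel_size, frame: int
) -> NucleusSegment:
    mask = label_img[sl] == label
    count = int(mask.sum())
    idx = np.nonzero(mask)
    centroid = tuple(
        float((idx[a].mean() + sl[a].start) * voxel_size[a]) for a in range(3)
    )
    shape = label_img.shape
    touches = any(
        (sl[a].start == 0 and idx[a].min() == 0)
        or (sl[a].stop == shape[a] and idx[a].max() == mask.shape[a] - 1)
        for a in range(3)
    )
    return NucleusSegment(
        label=label,
        slices=sl,
        mask=mask,
        centroid=centroid,
        volume=count * float(np.prod(voxel_size)),
        voxel_count=count,
        frame=frame,
        touches_border=touches,
    )


def _pad_slices(sl, shape, pad_vox):
    return tuple(
        slice(max(0, s.start - p), min(n, s.stop + p))
        for s, p, n in zip(sl, pad_vox, shape)
    )


def _refine_component(
    stack: np.ndarray,
    seg: NucleusSegment,
    region: np.ndarray,
    voxel_size,
    pad_um: float,
    tol: float,
    max_iter: int,
    frame: int,
):
    """Iterative local re-thresholding of one seed component.

    Recomputes Otsu inside the component's padded bounding box — restricted
    to the embryo ``region`` so that out-of-cap background cannot drag the
    local threshold down to the background/cytoplasm split — re-binarizes,
    keeps the connected component containing the previous centroid, and
    iterates until the voxel set changes by less than ``tol`` (fraction) or
    ``max_iter`` iterations. Returns the refined segment.
    """
    shape = stack.shape
    pad_vox = [max(1, int(np.ceil(pad_um / s))) for s in voxel_size]
    mask_full_prev = seg.full_mask(shape)
    current = seg
    for _ in range(max_iter):
        sl = _pad_slices(current.slices, shape, pad_vox)
        local = stack[sl]
        local_region = region[sl]
        t = _safe_otsu(local[local_region])
        if t is None:
            break
        binar = (local > t) & local_region
        binar = ndimage.binary_fill_holes(binar, structure=None)
        lab, n = ndimage.label(binar, structure=STRUCT_26)
        if n == 0:
            break
        cz = tuple(
            int(round(current.centroid[a] / voxel_size[a])) - sl[a].start
            for a in range(3)
        )
        cz = tuple(np.clip(cz[a], 0, lab.shape[a] - 1) for a in range(3))
        keep = lab[cz]
        if keep == 0:
            # centroid voxel fell below the local threshold: stop and keep
            # the previous voxel set rather than drifting onto a brighter
            # neighbouring object (the caller recycles any voxels this
            # leaves unclaimed)
            break
        new_full = np.zeros(shape, dtype=bool)
        new_full[sl][lab == keep] = True
        changed = np.logical_xor(new_full, mask_full_prev).sum()
        objs = ndimage.find_objects(new_full.astype(np.int8))
        current = _component_segment(new_full.astype(np.int8), 1, objs[0], voxel_size, frame)
        current.label = seg.label
        if changed < tol * max(1, mask_full_prev.sum()):
            mask_full_prev = new_full
            break
        mask_full_prev = new_full
    current.touches_border = seg.touches_border or current.touches_border
    return current


def segment_nuclei(
    stack: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_volume: float = 30.0,
    cap_mask: np.ndarray | None = None,
    pad_um: float = 4.0,
    tol: float = 0.01,
    max_iter: int = 10,
    frame: int = 0,
    refine: bool = True,
    denoise_size: int = 0,
) -> list[NucleusSegment]:
    """Segment nuclei by seed thresholding plus per-nucleus local refinement.

    Parameters
    ----------
    stack : ndarray
        3D (ZYX) nuclear-marker intensity image.
    voxel_size : tuple
        Physical voxel size (z, y, x) in µm.
    min_volume : float
        Minimum accepted nucleus volume in µm³ (suppresses noise specks).
    cap_mask : ndarray, optional
        Restrict the seed-threshold estimation to the animal cap.
    refine : bool
        Run the per-component iterative local-Otsu refinement.
    denoise_size : int
        Median-filter window (voxels) applied for mask determination only.
        Needed when nuclei occupy a small volume fraction at low contrast:
        on the raw histogram the upper noise tail of the cytoplasm
        out-weighs the nucleus class and Otsu locks onto noise. A median
        filter suppresses those tails while preserving edge positions and
        small objects (a Gaussian blur of comparable strength smears both).
        The default of 0 keeps noise-free segmentation exact. Intensity
        statistics are always taken from the raw stack by the caller.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.size == 0 or not np.any(stack):
        return []
    if denoise_size > 1:
        # lateral-only window: axial sampling is coarse, and a 3D window
        # erodes the polar planes of small nuclei
        stack = ndimage.median_filter(stack, size=(1, denoise_size, denoise_size))
    voxel_vol = float(np.prod(voxel_size))
    min_vox = max(1, int(round(min_volume / voxel_vol)))

    nuclear_mask, region = _seed_threshold(stack, cap_mask)
    if nuclear_mask is None or not nuclear_mask.any():
        return []
    nuclear_mask = ndimage.binary_fill_holes(nuclear_mask)
    lab, n = ndimage.label(nuclear_mask, structure=STRUCT_26)
    objects = ndimage.find_objects(lab)
    seeds = []
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        seg = _component_segment(lab, i, sl, voxel_size, frame)
        if seg.voxel_count >= min_vox:
            seeds.append(seg)

    if not refine:
        for i, seg in enumerate(seeds, start=1):
            seg.label = i
        return seeds

    # Refine every seed, then recycle seed voxels not claimed by any refined
    # segment: a merged seed whose local threshold keeps only its brightest
    # nucleus leaves the dimmer one(s) behind as residual components, which
    # are refined in turn.
    refined: list[NucleusSegment] = []
    seed_union = np.zeros(stack.shape, dtype=bool)
    for seg in seeds:
        seed_union[seg.slices][seg.mask] = True
    covered = np.zeros(stack.shape, dtype=bool)
    queue = list(seeds)
    for _ in range(3):  # initial pass + residual recycling passes
        for seg in queue:
            out = _refine_component(
                stack, seg, region, voxel_size, pad_um, tol, max_iter, frame
            )
            mask = out.full_mask(stack.shape) & ~covered
            count = int(mask.sum())
            if count < min_vox:
                continue
            sl = ndimage.find_objects(mask.astype(np.int8))[0]
            final = _component_segment(mask.astype(np.int8), 1, sl, voxel_size, frame)
            final.touches_border = out.touches_border
            refined.append(final)
            covered |= mask
        residual = seed_union & ~covered
        lab_res, _ = ndimage.label(residual, structure=STRUCT_26)
        queue = [
            piece
            for i, sl in enumerate(ndimage.find_objects(lab_res), start=1)
            if sl is not None
            and (piece := _component_segment(lab_res, i, sl, voxel_size, frame)).voxel_count
            >= min_vox
        ]
        seed_union = covered  # recycle each residual component once
        if not queue:
            break
    for i, seg in enumerate(refined, start=1):
        seg.label = i
    return refined


def nuclei_mask(segments: list[NucleusSegment], shape) -> np.ndarray:
    """Union mask of all segmented nuclei."""
    out = np.zeros(shape, dtype=bool)
    for seg in segments:
        out[seg.slices][seg.mask] = True
    return out


def cytoplasm_shell(
    segment: NucleusSegment,
    all_nuclei_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    step: float = 2.0,
    within: np.ndarray | None = None,
) -> np.ndarray:
    """Cytoplasmic sampling shell around one nucleus.

    The nucleus mask is dilated in two steps of ``step`` µm (dilation by a
    physical distance r is thresholding the Euclidean distance transform at
    r, which is exact under anisotropic voxels); the once-extended shell and
    every nucleus voxel are removed from the twice-extended shell:

        shell = dilate(mask, 2·step) − dilate(mask, step) − all_nuclei

    ``within``, if given, additionally restricts the shell to a region mask
    (typically the segmented animal cap, so that shells of surface-proximal
    nuclei do not sample dark out-of-embryo voxels).

    Returns a full-size boolean mask; an all-False result means the nucleus
    is fully surrounded by other nuclei and should be excluded from ratio
    statistics (the caller flags this).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    shape = all_nuclei_mask.shape
    pad_vox = [int(np.ceil(2 * step / s)) + 1 for s in voxel_size]
    sl = _pad_slices(segment.slices, shape, pad_vox)
    local = np.zeros(tuple(s.stop - s.start for s in sl), dtype=bool)
    inner = tuple(
        slice(a.start - b.start, a.stop - b.start) for a, b in zip(segment.slices, sl)
    )
    local[inner][segment.mask] = True
    dist = ndimage.distance_transform_edt(~local, sampling=voxel_size)
    shell_local = (dist > step) & (dist <= 2 * step)
    shell = np.zeros(shape, dtype=bool)
    shell[sl] = shell_local
    shell &= ~all_nuclei_mask
    if within is not None:
        shell &= within
    return shell


def nc_ratio(
    stack: np.ndarray,
    segment: NucleusSegment,
    shell: np.ndarray,
    background: float = 0.0,
) -> NucleusSegment:
    """Background-corrected nuclear-over-cytoplasmic intensity ratio.

    R = (mean_nuclear − background) / (mean_shell − background). An empty
    shell or a non-positive denominator marks the segment invalid; a negative
    R is never returned silently.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    nuc_vals = stack[segment.slices][segment.mask]
    segment.mean_nuclear_intensity = float(nuc_vals.mean())
    if not shell.any():
        segment.valid_ratio = False
        segment.nc_ratio = float("nan")
        log.warning("nucleus %d: empty cytoplasm shell, excluded", segment.label)
        return segment
    shell_vals = stack[shell]
    segment.mean_shell_intensity = float(shell_vals.mean())
    denom = segment.mean_shell_intensity - background
    numer = segment.mean_nuclear_intensity - background
    if denom <= 0 or numer < 0:
        segment.valid_ratio = False
        segment.nc_ratio = float("nan")
        log.warning("nucleus %d: invalid background-corrected ratio", segment.label)
        return segment
    segment.nc_ratio = numer / denom
    segment.valid_ratio = True
    return segment


def filter_interphase(segments: list[NucleusSegment], threshold: float = 2.0) -> list[NucleusSegment]:
    """Keep only nuclei with a valid ratio strictly above ``threshold``.

    The R > 2 cut-off removes nuclei that are not in interphase or whose
    signal is degraded; the number excluded is logged.
    """
    kept = [
        s
        for s in segments
        if s.valid_ratio and np.isfinite(s.nc_ratio) and s.nc_ratio > threshold
    ]
    log.info("interphase filter: kept %d of %d nuclei", len(kept), len(segments))
    return kept


def segment_cap(
    stack: np.ndarray,
    voxel_size: tuple[float, float, float],
    mode: str = "3d",
    smooth_sigma_um: float = 0.0,
) -> CapSegmentation:
    """Segment the animal cap with a single global threshold.

    The threshold is derived from the 256-bin histogram of the
    maximum-intensity z-projection. Because a nuclear-labelled stack is
    three-level (background / cytoplasm / bright nuclei), a three-class
    multi-Otsu is attempted and its lower threshold taken (separating
    background from embryo); on images without a third mode this falls back
    to plain two-class Otsu. In ``"3d"`` mode the threshold is applied to
    all 3D voxels (default); ``"2d"`` extrudes the projected mask along z.
    The largest 26-connected component is kept.

    ``smooth_sigma_um`` applies an isotropic (physical-units) Gaussian blur
    before thresholding. On noisy stacks this is essential: the maximum
    projection rides on the upper tail of the noise, so its threshold sits
    above the cytoplasm mode of the raw voxel histogram and would punch
    holes through the cap. The default of 0 keeps noise-free segmentation
    exact.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if smooth_sigma_um > 0:
        sigma_vox = [smooth_sigma_um / s for s in voxel_size]
        stack = ndimage.gaussian_filter(stack, sigma=sigma_vox)
    mip = stack.max(axis=0)
    # Bright nuclei smear across a wide intensity range in the projection
    # and would drag a plain Otsu threshold toward (or past) the cytoplasm
    # level. Two-stage scheme: a 2-class Otsu on the log-compressed
    # projection (log shrinks the nucleus tail) gives a rough
    # background/embryo split; the final threshold is the midpoint of the
    # two class medians, which is insensitive to the nucleus tail for any
    # nucleus brightness and sits halfway between the background and
    # cytoplasm modes (zero boundary bias under symmetric noise).
    log_mip = np.log1p(np.clip(mip, 0, None))
    t_rough = _safe_otsu(log_mip.ravel())
    if t_rough is None:
        raise ValueError("cannot segment cap: projection is constant")
    below = mip[log_mip <= t_rough]
    above = mip[log_mip > t_rough]
    threshold = float(np.median(below) + np.median(above)) / 2.0
    if mode == "3d":
        mask = stack > threshold
    elif mode == "2d":
        mask = np.broadcast_to(mip > threshold, stack.shape).copy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lab, n = ndimage.label(mask, structure=STRUCT_26)
    if n == 0:
        raise ValueError("cap segmentation produced an empty mask")
    counts = np.bincount(lab.ravel())[1:]
    keep = int(np.argmax(counts)) + 1
    cap = lab == keep
    return CapSegmentation(
        mask=cap,
        cap_volume=float(cap.sum()) * float(np.prod(voxel_size)),
        threshold=threshold,
    )


def track_nuclei(
    frame_segments: list[list[NucleusSegment]],
    max_link_dist: float | None = None,
) -> list[Track]:
    """Link nuclei across consecutive frames by minimal centroid distance.

    Greedy mutual-nearest matching: candidate links are sorted by distance
    (ties broken by lowest label) and accepted when both endpoints are still
    unmatched and the distance is within ``max_link_dist`` (default: twice
    the median nuclear radius estimated from segment volumes). Unmatched
    next-frame segments start new tracks; unmatched previous-frame segments
    terminate.
    """
    if len(frame_segments) < 1:
        return []
    if max_link_dist is None:
        vols = [s.volume for segs in frame_segments for s in segs]
        if vols:
            median_r = (3.0 * float(np.median(vols)) / (4.0 * np.pi)) ** (1.0 / 3.0)
            max_link_dist = 2.0 * median_r
        else:
            max_link_dist = np.inf

    tracks: list[Track] = []
    open_by_label: dict[int, Track] = {}
    next_id = 1
    for seg in frame_segments[0]:
        t = Track(next_id)
        t.add(0, seg.label, seg.volume)
        open_by_label[seg.label] = t
        tracks.append(t)
        next_id += 1

    for f in range(1, len(frame_segments)):
        prev, curr = frame_segments[f - 1], frame_segments[f]
        candidates = []
        for p in prev:
            for c in curr:
                d = float(
                    np.linalg.norm(np.array(p.centroid) - np.array(c.centroid))
                )
                if d <= max_link_dist:
                    candidates.append((d, p.label, c.label))
        candidates.sort()
        matched_prev: set[int] = set()
        matched_curr: set[int] = set()
        links: dict[int, int] = {}
        for d, pl, cl in candidates:
            if pl in matched_prev or cl in matched_curr:
                continue
            matched_prev.add(pl)
            matched_curr.add(cl)
            links[cl] = pl
        new_open: dict[int, Track] = {}
        for c in curr:
            if c.label in links and links[c.label] in open_by_label:
                t = open_by_label[links[c.label]]
                t.add(f, c.label, c.volume)
            else:
                t = Track(next_id)
                next_id += 1
                t.add(f, c.label, c.volume)
                tracks.append(t)
            new_open[c.label] = t
        open_by_label = new_open
    return tracks


def volume_fraction(tracks: list[Track], cap: CapSegmentation) -> float:
    """Nuclear volume fraction v from per-track maximal-extension volumes.

    v = Σ_tracks max-volume-within-track / cap_volume. Using each track's
    volume at maximal extension (rather than a time average) matches how the
    nuclear volume budget of a stage is defined over a cell cycle.
    """
    total = sum(t.max_extension_volume for t in tracks)
    v = total / cap.cap_volume
    if v >= 1:
        raise ValueError(f"nuclear volume fraction {v:.3f} >= 1: nuclei exceed cap")
    return v


def count_cells(
    stack: np.ndarray,
    voxel_size: tuple[float, float, float],
    **segment_kwargs,
) -> int:
    """Count cells as the number of accepted nuclear segments."""
    return len(segment_nuclei(stack, voxel_size, **segment_kwargs))
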