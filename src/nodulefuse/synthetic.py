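"""Synthetic LIDC-like cohort generator.

Generates annotated nodules with the statistical structure the pipeline
assumes, so every downstream stage (pseudo-labeling, radiomics, the 3D CNN,
fusion, evaluation) is testable without any image archive.

Model
-----
A single latent malignancy driver ``m ~ Uniform(0, 1)`` per nodule controls

* the ordinal 1-5 malignancy category, by thresholding ``m`` so the
  realized intermediate (R3) fraction matches the configured fraction
  (default 0.374) up to binomial sampling error;
* the ordinal biomarker means, through a linear link with per-marker signed
  weights (spiculation/lobulation/subtlety increase with ``m``;
  calcification/margin decrease, emulating their benign associations)
  plus Gaussian jitter, then rounding and clamping to each ordinal range;
* nodule size and shape: the equivalent-sphere radius grows linearly with
  ``m``, and the number of surface spikes grows with the sampled
  spiculation score.

The generator makes no claim of marginal fidelity to any real archive; it
provides controllable, monotone malignancy signal in both biomarker space
and image space.  All knobs live in :class:`GeneratorConfig`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .data import BIOMARKER_NAMES, BIOMARKER_RANGES, NoduleRecord, save_cohort
from .exceptions import ConfigurationError, GenerationError

#: Signed link weight of each biomarker to the latent malignancy driver.
#: Positive: marker increases with malignancy suspicion.  Magnitudes chosen
#: so that at the default effect size the strongest marker (spiculation)
#: saturates its scale at the latent extremes.
MARKER_WEIGHTS = {
    "subtlety": 0.8,
    "int_structure": 0.0,
    "calcification": -0.6,
    "sphericity": -0.3,
    "margin": -0.4,
    "lobulation": 0.9,
    "spiculation": 1.0,
    "texture": 0.3,
}

#: Nodule base radius range in mm mapped linearly onto latent [0, 1].
RADIUS_MIN_MM = 2.0
RADIUS_MAX_MM = 5.0
#: Spikes reach out to this multiple of the local ellipsoid radius.
SPIKE_REACH = 1.3


@dataclass
class GeneratorConfig:
    """All tunable knobs of the synthetic cohort generator."""

    n_nodules: int = 1000
    r3_fraction: float = 0.374
    class_balance: float = 0.5  # suspicious (R45) share among non-R3 nodules
    biomarker_effect: float = 1.0
    noise_sd: float = 2.0
    size_jitter: float = 0.3  # latent-scale noise on the size driver
    volume_shape: tuple[int, int, int] = (32, 32, 16)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r3_fraction <= 1.0:
            raise ConfigurationError(f"r3_fraction must be in [0,1]: {self.r3_fraction}")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ConfigurationError(f"class_balance must be in [0,1]: {self.class_balance}")
        if self.biomarker_effect < 0:
            raise ConfigurationError("biomarker_effect must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.size_jitter < 0:
            raise ConfigurationError("size_jitter must be non-negative")
        if any(int(s) <= 0 for s in self.volume_shape):
            raise ConfigurationError(f"volume_shape must be positive: {self.volume_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"spacing_mm must be positive: {self.spacing_mm}")

    @property
    def latent_thresholds(self) -> tuple[float, float]:
        """(t1, t2): latent < t1 -> R12, t1 <= latent < t2 -> R3, else R45."""
        p12 = (1.0 - self.r3_fraction) * (1.0 - self.class_balance)
        return p12, p12 + self.r3_fraction


def sample_biomarkers(
    config: GeneratorConfig, latent: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw the 8 ordinal biomarker scores for one nodule.

    Each marker's mean sits at ``0.5 + effect * weight * (latent - 0.5)``
    of its ordinal range (clipped), with Gaussian jitter of ``noise_sd``
    scale units added before rounding and clamping.
    """
    if not 0.0 <= latent <= 1.0:
        raise ConfigurationError(f"latent must be in [0,1], got {latent}")
    out = np.empty(len(BIOMARKER_NAMES), dtype=int)
    for i, name in enumerate(BIOMARKER_NAMES):
        lo, hi = BIOMARKER_RANGES[name]
        pos = 0.5 + config.biomarker_effect * MARKER_WEIGHTS[name] * (latent - 0.5)
        pos = min(max(pos, 0.0), 1.0)
        raw = lo + (hi - lo) * pos
        if config.noise_sd > 0:
            raw += rng.normal(0.0, config.noise_sd)
        out[i] = int(np.clip(round(raw), lo, hi))
    return out


def render_nodule(
    biomarkers: np.ndarray,
    latent: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one nodule volume and mask.

    The mask is a centered ellipsoid (semi-axes jittered around a base
    radius that grows linearly with ``latent``) plus radial spikes whose
    count grows with the spiculation score.  The volume is Gaussian
    background noise with elevated intensity inside the mask.
    """
    if not 0.0 <= latent <= 1.0:
        raise ConfigurationError(f"latent must be in [0,1], got {latent}")
    shape = tuple(int(s) for s in config.volume_shape)
    spacing = np.asarray(config.spacing_mm, dtype=float)
    axis_jitter = rng.uniform(0.85, 1.15, size=3)
    # size tracks malignancy imperfectly: large benign and small suspicious
    # nodules both occur, so image-only classification stays non-trivial
    size_driver = float(latent)
    if config.size_jitter > 0:
        size_driver = float(
            np.clip(latent + rng.normal(0.0, config.size_jitter), 0.0, 1.0)
        )
    r_mm = RADIUS_MIN_MM + (RADIUS_MAX_MM - RADIUS_MIN_MM) * size_driver
    semi_mm = r_mm * axis_jitter  # physical semi-axes

    half_extent_mm = np.array(shape) / 2.0 * spacing
    if (semi_mm * SPIKE_REACH >= half_extent_mm).any():
        raise GenerationError(
            f"nodule radius {semi_mm.max():.1f} mm (with spikes) exceeds half "
            f"the grid extent {half_extent_mm.min():.1f} mm"
        )

    # physical coordinates of voxel centers relative to the grid center
    centers = [(np.arange(shape[i]) - (shape[i] - 1) / 2.0) * spacing[i] for i in range(3)]
    xx, yy, zz = np.meshgrid(*centers, indexing="ij")
    mask = (xx / semi_mm[0]) ** 2 + (yy / semi_mm[1]) ** 2 + (zz / semi_mm[2]) ** 2 <= 1.0

    spiculation = int(biomarkers[BIOMARKER_NAMES.index("spiculation")])
    spic_lo = BIOMARKER_RANGES["spiculation"][0]
    n_spikes = 2 * (spiculation - spic_lo)
    if n_spikes > 0:
        pts = np.stack([xx, yy, zz])  # (3, X, Y, Z), mm
        for _ in range(n_spikes):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # ellipsoid radius along direction u
            r_dir = 1.0 / np.sqrt(((u / semi_mm) ** 2).sum())
            proj = np.einsum("i,i...->...", u, pts)
            perp = np.sqrt(np.maximum((pts**2).sum(axis=0) - proj**2, 0.0))
            mask |= (proj >= 0.7 * r_dir) & (proj <= SPIKE_REACH * r_dir) & (perp <= 0.9)

    volume = rng.normal(0.0, 1.0, size=shape)
    volume[mask] += 2.5 + 0.2 * rng.normal(size=int(mask.sum()))
    return volume.astype(np.float32), mask


def _malignancy_from_latent(latent: float, config: GeneratorConfig) -> int:
    t1, t2 = config.latent_thresholds
    if latent < t1:
        return 1 if latent < t1 / 2.0 else 2
    if latent < t2:
        return 3
    return 4 if latent < (t2 + 1.0) / 2.0 else 5


def latent_side(latent: float, config: GeneratorConfig) -> int:
    """Ground-truth binary side of a latent value (0 benign / 1 suspicious).

    The R3 band is split at its midpoint; used as the oracle when scoring
    pseudo-label recovery on synthetic cohorts.
    """
    t1, t2 = config.latent_thresholds
    return int(latent >= (t1 + t2) / 2.0)


def generate_cohort(
    config: GeneratorConfig, return_latent: bool = False
) -> list[NoduleRecord] | tuple[list[NoduleRecord], np.ndarray]:
    """Generate a full synthetic cohort of :class:`NoduleRecord`.

    Deterministic for a fixed config (including seed).  Synthetic patient
    ids group two nodules per patient so patient-level splitting can be
    exercised.
    """
    if config.n_nodules < 10:
        raise ConfigurationError(f"n_nodules must be >= 10, got {config.n_nodules}")
    rng = np.random.default_rng(config.seed)
    latents = rng.uniform(0.0, 1.0, size=config.n_nodules)
    records = []
    for i, latent in enumerate(latents):
        biomarkers = sample_biomarkers(config, float(latent), rng)
        volume, mask = render_nodule(biomarkers, float(latent), config, rng)
        records.append(
            NoduleRecord(
                patient_id=f"SYN-{i // 2:04d}",
                **{n: int(v) for n, v in zip(BIOMARKER_NAMES, biomarkers)},
                malignancy=_malignancy_from_latent(float(latent), config),
                volume=volume,
                mask=mask,
                spacing_mm=tuple(config.spacing_mm),
            )
        )
    if return_latent:
        return records, latents
    return records


# ---------------------------------------------------------------------------
# Fixture XML writing (round-trips through nodulefuse.lidc)
# ---------------------------------------------------------------------------

def _trace_boundary(region: np.ndarray) -> list[tuple[int, int]]:
    """Ordered closed boundary chain of a connected 2-D region.

    Moore-neighbor tracing with Jacob's stopping criterion; returns pixel
    (row, col) coordinates of the outer boundary, clockwise.
    """
    pts = np.argwhere(region)
    if len(pts) == 0:
        return []
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    start = tuple(pts[order[0]])  # uppermost-leftmost: west neighbor empty
    if len(pts) == 1:
        return [start]
    # clockwise Moore neighborhood starting from west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]

    def occupied(p):
        return (
            0 <= p[0] < region.shape[0]
            and 0 <= p[1] < region.shape[1]
            and region[p[0], p[1]]
        )

    chain = [start]
    cur = start
    prev_dir = 0  # entered from the west
    first_move = None
    for _ in range(8 * region.size):  # safety bound; trace terminates well before
        for step in range(8):
            d = (prev_dir + step) % 8
            cand = (cur[0] + nbrs[d][0], cur[1] + nbrs[d][1])
            if occupied(cand):
                break
        else:
            return chain  # isolated pixel
        if first_move is None:
            first_move = (cur, d)
        elif (cur, d) == first_move:
            break  # about to repeat the very first move: boundary closed
        cur = cand
        chain.append(cur)
        prev_dir = (d + 5) % 8  # restart scan just past the backtrack pixel
    if len(chain) > 1 and chain[-1] == chain[0]:
        chain.pop()
    return chain


def _repair_chain(
    chain: list[tuple[int, int]], core: np.ndarray
) -> list[tuple[int, int]]:
    """Add spur excursions so the filled chain interior equals ``core``.

    The traced outer boundary can skip outline pixels sitting in one-pixel
    notches; visiting them via a doubled edge (out and straight back)
    leaves the even-odd fill unchanged while adding them to the excluded
    outline set, restoring the exact round trip.
    """
    from .lidc import polygon_interior

    for _ in range(8):  # each pass peels one layer of unvisited notch pixels
        interior = polygon_interior(chain, core.shape)
        pts = np.array(chain)
        interior[pts[:, 0], pts[:, 1]] = False
        extras = np.argwhere(interior & ~core)
        if len(extras) == 0:
            break
        chain_set = {tuple(p) for p in chain}
        progressed = False
        for ex in map(tuple, extras):
            if ex in chain_set:
                continue
            for i, (cx, cy) in enumerate(chain):
                if max(abs(cx - ex[0]), abs(cy - ex[1])) == 1:
                    chain = chain[: i + 1] + [ex, (cx, cy)] + chain[i + 1 :]
                    chain_set.add(ex)
                    progressed = True
                    break
        if not progressed:
            break
    return chain


def _slice_contours(mask_slice: np.ndarray) -> list[list[tuple[int, int]]]:
    """Outline contours of one mask slice, at the first pixel outside.

    The slice is dilated by one pixel (4-neighborhood) and the boundary of
    each connected dilated component is traced, matching the LIDC
    convention that contour pixels lie just outside the nodule.
    """
    from scipy import ndimage

    cross = ndimage.generate_binary_structure(2, 1)
    dilated = ndimage.binary_dilation(mask_slice, structure=cross)
    labels, n = ndimage.label(dilated, structure=np.ones((3, 3), dtype=bool))
    contours = []
    for comp in range(1, n + 1):
        region = labels == comp
        chain = _trace_boundary(region)
        if chain:
            contours.append(_repair_chain(chain, mask_slice & region))
    return contours


def write_fixture_xml(records: list[NoduleRecord], path: str) -> None:
    """Write records as a LIDC-style XML annotation file.

    Per-slice edge contours (x, y pixel coordinates) with z-positions in mm,
    plus the 9 characteristic scores, in the dialect read by
    :func:`nodulefuse.lidc.parse_annotations`.  Contour pixels are placed at
    the first pixel outside the nodule, so parsing + rasterizing recovers
    the original mask interiors.
    """
    from .lidc import CHARACTERISTIC_TAGS  # local import to avoid cycle

    root = etree.Element("LidcReadMessage")
    header = etree.SubElement(root, "ResponseHeader")
    etree.SubElement(header, "SeriesInstanceUid").text = "synthetic"
    session = etree.SubElement(root, "readingSession")
    etree.SubElement(session, "servicingRadiologistID").text = "synthetic-reader"
    for idx, rec in enumerate(records):
        nod = etree.SubElement(session, "unblindedReadNodule")
        etree.SubElement(nod, "noduleID").text = f"{rec.patient_id}-n{idx}"
        chars = etree.SubElement(nod, "characteristics")
        for name, tag in CHARACTERISTIC_TAGS.items():
            etree.SubElement(chars, tag).text = str(
                int(rec.malignancy) if name == "malignancy" else int(getattr(rec, name))
            )
        sz = rec.spacing_mm[2]
        for z in range(rec.mask.shape[2]):
            mask_slice = rec.mask[:, :, z]
            if not mask_slice.any():
                continue
            for chain in _slice_contours(mask_slice):
                roi = etree.SubElement(nod, "roi")
                etree.SubElement(roi, "imageZposition").text = f"{z * sz:.3f}"
                etree.SubElement(roi, "inclusion").text = "TRUE"
                for x, y in chain:
                    edge = etree.SubElement(roi, "edgeMap")
                    etree.SubElement(edge, "xCoord").text = str(int(x))
                    etree.SubElement(edge, "yCoord").text = str(int(y))
    tree = etree.ElementTree(root)
    tree.write(path, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def synth_to_dir(config: GeneratorConfig, out_dir: str, with_xml: bool = False) -> None:
    """Generate a cohort and serialize it (CSV + array container, opt. XML)."""
    records = generate_cohort(config)
    save_cohort(records, out_dir)
    if with_xml:
        write_fixture_xml(records, os.path.join(out_dir, "annotations.xml"))
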