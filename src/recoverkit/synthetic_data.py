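"""Ground-truthed simulators for every pipeline stage.

The study's raw data (screen plates, confocal images, junction clone reads)
are not deposited, so each generator emulates the corresponding
data-generating process and returns the planted truth alongside the dataset:

* :func:`simulate_screen` — a multi-plate siRNA screen (529 genes, 4 oligos
  per gene, luciferase / PPM1D / βTrCP control wells on every plate) with
  Gaussian well-to-well noise on the mitotic fraction and planted hit genes
  shifted by a stated number of null SDs.
* :func:`simulate_images` — DAPI + focus-channel scenes: noisy filled
  ellipses for nuclei and isotropic 2D Gaussian spots for foci, optionally
  spread over a z-stack.
* :func:`simulate_junction_reads` — repair-junction reads drawn from the
  four event categories with controlled deletion sizes, insertion lengths
  and microhomology.

Determinism: every artifact draws from its own ``numpy`` Generator seeded by
``SeedSequence([ARTIFACT_KEY, seed])``, so regenerating one dataset never
perturbs another and identical specs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .junction_caller import ReferenceAmplicon, microhomology

# artifact keys for per-generator RNG streams
_KEY_SCREEN, _KEY_IMAGES, _KEY_JUNCTIONS, _KEY_REFERENCE = 101, 102, 103, 104


def _rng(artifact_key: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([artifact_key, int(seed)]))


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedHit:
    gene: str
    direction: Literal["increased", "decreased"]
    effect_size_sd: float = 5.0
    fraction_effective_oligos: float = 1.0


@dataclass
class ScreenSimSpec:
    """Study conditions of the primary screen.

    Defaults follow the screened library (529 genes, four oligos per gene,
    96-well plates carrying luciferase / PPM1D / βTrCP control wells, three
    replicates).  The well readout is the mitotic (pHH3-positive) fraction
    after IR; its null distribution is Gaussian, truncated to [0, 1] — the
    level and spread are stated modelling assumptions, not reported values.
    """

    n_genes: int = 529
    oligos_per_gene: int = 4
    n_replicates: int = 3
    wells_per_plate: int = 96
    null_mean: float = 0.25
    null_sd: float = 0.04
    pooled: bool = True  # one SMARTpool well per gene; False = per-oligo wells
    planted_hits: tuple[PlantedHit, ...] = ()
    control_effects: dict = field(
        default_factory=lambda: {"PPM1D": -4.0, "BTRC": -4.0}
    )  # positive-control shifts in null SDs
    seed: int = 0


def default_hit_structure(genes: Sequence[str], effect_size_sd: float = 5.0) -> tuple[PlantedHit, ...]:
    """The screen's hit structure: 28 decreased- and 13 increased-recovery genes.

    Hit genes are spread evenly through the library (hits are not clustered
    on one plate in a real screen); the default effect size corresponds to a
    strong knockdown phenotype — a shift of five well-to-well SDs, i.e.
    near-complete loss (or a doubling) of mitotic entry on the default
    readout scale.
    """
    if len(genes) < 41:
        raise ValueError("need at least 41 genes for the 28+13 hit structure")
    idx = np.linspace(0, len(genes) - 1, 41).round().astype(int)
    chosen = [genes[i] for i in idx]
    # interleave the directions so no plate is dominated by one sign
    increased_slots = set(np.linspace(0, 40, 13).round().astype(int))
    return tuple(
        PlantedHit(g, "increased" if i in increased_slots else "decreased", effect_size_sd)
        for i, g in enumerate(chosen)
    )


def simulate_screen(spec: ScreenSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a screen; returns (screen table, planted-truth table).

    Control wells (negative: luciferase; positive: PPM1D, βTrCP) are placed
    on every plate.  Planted hits shift the treated readout of their
    effective oligos by ``effect_size_sd x null_sd`` in the stated direction.
    """
    rng = _rng(_KEY_SCREEN, spec.seed)
    genes = [f"GENE{i:04d}" for i in range(1, spec.n_genes + 1)]
    planted = {h.gene: h for h in spec.planted_hits}
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes absent from gene list: {sorted(unknown)}")

    oligo_ids = (
        ["pool"] if spec.pooled else [f"oligo{i}" for i in range(1, spec.oligos_per_gene + 1)]
    )
    sample_units = [(g, o) for g in genes for o in oligo_ids]
    controls = [("LUC", "pool", "negative_control")] + [
        (g, "pool", "positive_control") for g in spec.control_effects
    ]
    n_ctrl = len(controls)
    samples_per_plate = spec.wells_per_plate - n_ctrl

    # which oligos of each planted gene actually carry the effect
    effective: dict[tuple[str, str], float] = {}
    for h in spec.planted_hits:
        k = max(1, round(h.fraction_effective_oligos * len(oligo_ids)))
        sign = 1.0 if h.direction == "increased" else -1.0
        for o in oligo_ids[:k]:
            effective[(h.gene, o)] = sign * h.effect_size_sd
    for g, eff in spec.control_effects.items():
        effective[(g, "pool")] = eff

    rows = []
    for rep in range(1, spec.n_replicates + 1):
        for p_start in range(0, len(sample_units), samples_per_plate):
            plate_units = sample_units[p_start : p_start + samples_per_plate]
            plate_id = f"P{p_start // samples_per_plate + 1:02d}"
            well_idx = 0
            for g, o, ctl in controls:
                shift = effective.get((g, o), 0.0) * spec.null_sd
                x = rng.normal(spec.null_mean + shift, spec.null_sd)
                rows.append(
                    dict(
                        plate_id=plate_id,
                        well_id=f"W{well_idx:03d}",
                        gene=g,
                        sirna_id=o,
                        condition="treated",
                        replicate=rep,
                        readout=float(np.clip(x, 0.0, 1.0)),
                        is_control=ctl,
                    )
                )
                well_idx += 1
            for g, o in plate_units:
                shift = effective.get((g, o), 0.0) * spec.null_sd
                x = rng.normal(spec.null_mean + shift, spec.null_sd)
                rows.append(
                    dict(
                        plate_id=plate_id,
                        well_id=f"W{well_idx:03d}",
                        gene=g,
                        sirna_id=o,
                        condition="treated",
                        replicate=rep,
                        readout=float(np.clip(x, 0.0, 1.0)),
                        is_control="none",
                    )
                )
                well_idx += 1

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            dict(
                gene=h.gene,
                direction=h.direction,
                effect_size_sd=h.effect_size_sd,
                fraction_effective_oligos=h.fraction_effective_oligos,
            )
            for h in spec.planted_hits
        ],
        columns=["gene", "direction", "effect_size_sd", "fraction_effective_oligos"],
    )
    return table, truth


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclass
class ImageSimSpec:
    """Confocal-scene conditions: nucleus geometry, focus photometry, noise.

    Focus amplitude is specified in units of the background noise SD so
    SNR-based detection claims are well defined; the default (8x) emulates
    bright IRIF shortly after irradiation.
    """

    image_size: tuple[int, int] = (512, 512)
    n_nuclei: int = 5
    nucleus_semiaxes: tuple[tuple[float, float], tuple[float, float]] = ((18.0, 28.0), (14.0, 22.0))
    foci_per_nucleus: int | tuple[str, float] = 10  # int or ("poisson", mean)
    focus_amplitude_snr: float = 8.0
    focus_sigma: float = 1.5
    background: float = 100.0
    noise: tuple[str, float] = ("gaussian", 10.0)  # ("gaussian", sd) or ("poisson", scale)
    dapi_foreground: float = 150.0
    dapi_background: float = 20.0
    z_planes: int = 1
    min_focus_separation: float = 7.0
    allow_border: bool = False
    seed: int = 0


@dataclass
class ImageTruth:
    nuclei: pd.DataFrame  # nucleus_id, center_row, center_col, semi_r, semi_c, area
    foci: pd.DataFrame  # nucleus_id, row, col, amplitude, z_plane
    masks: np.ndarray  # planted integer label map


def _place_nuclei(spec: ImageSimSpec, rng: np.random.Generator) -> pd.DataFrame:
    h, w = spec.image_size
    rows = []
    attempts = 0
    while len(rows) < spec.n_nuclei:
        attempts += 1
        if attempts > 5000:
            raise ValueError("could not place requested nuclei without overlap")
        a = rng.uniform(*spec.nucleus_semiaxes[0])
        b = rng.uniform(*spec.nucleus_semiaxes[1])
        margin = 0 if spec.allow_border else max(a, b) + 3
        cr = rng.uniform(margin, h - margin)
        cc = rng.uniform(margin, w - margin)
        ok = all(
            np.hypot(cr - r["center_row"], cc - r["center_col"]) > (max(a, b) + max(r["semi_r"], r["semi_c"]) + 4)
            for r in rows
        )
        if ok:
            rows.append(dict(nucleus_id=len(rows) + 1, center_row=cr, center_col=cc, semi_r=a, semi_c=b))
    return pd.DataFrame(rows, columns=["nucleus_id", "center_row", "center_col", "semi_r", "semi_c"])


def simulate_images(spec: ImageSimSpec):
    """Simulate a two-channel scene; returns (ImageStack-ready dict, truth).

    The DAPI channel renders filled noisy ellipses; the focus channel renders
    isotropic Gaussian spots at recorded coordinates over a flat background
    plus noise.  With ``z_planes > 1`` each focus is placed in one plane so a
    maximum projection is required to see them all.  Returns
    ``({"dapi": ..., focus: ...}, ImageTruth)`` with arrays 2D or (z, y, x).
    """
    from .foci_imaging import ImageStack

    rng = _rng(_KEY_IMAGES, spec.seed)
    h, w = spec.image_size
    nuclei = _place_nuclei(spec, rng)

    masks = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]
    for r in nuclei.itertuples():
        inside = ((rr - r.center_row) / r.semi_r) ** 2 + ((cc - r.center_col) / r.semi_c) ** 2 <= 1.0
        masks[inside] = r.nucleus_id
    areas = {r.nucleus_id: int((masks == r.nucleus_id).sum()) for r in nuclei.itertuples()}
    nuclei["area"] = nuclei["nucleus_id"].map(areas)

    noise_kind, noise_scale = spec.noise

    # --- focus channel
    foci_rows = []
    for r in nuclei.itertuples():
        if isinstance(spec.foci_per_nucleus, tuple):
            kind, mean = spec.foci_per_nucleus
            if kind != "poisson":
                raise ValueError(f"unknown foci count distribution {kind!r}")
            n_foci = int(rng.poisson(mean))
        else:
            n_foci = int(spec.foci_per_nucleus)
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n_foci:
            attempts += 1
            if attempts > 20000:
                raise ValueError(
                    f"cannot place {n_foci} foci with separation {spec.min_focus_separation} "
                    f"inside nucleus {r.nucleus_id}"
                )
            # sample uniformly inside the ellipse, eroded so the full spot fits
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v > 1:
                continue
            shrink = 1 - (2.5 * spec.focus_sigma) / min(r.semi_r, r.semi_c)
            if shrink <= 0.1:
                shrink = 0.1
            fr = r.center_row + u * r.semi_r * shrink
            fc = r.center_col + v * r.semi_c * shrink
            if all(np.hypot(fr - pr, fc - pc) >= spec.min_focus_separation for pr, pc in placed):
                placed.append((fr, fc))
        for fr, fc in placed:
            z = int(rng.integers(spec.z_planes)) if spec.z_planes > 1 else 0
            foci_rows.append(
                dict(nucleus_id=r.nucleus_id, row=fr, col=fc,
                     amplitude=spec.focus_amplitude_snr * noise_scale, z_plane=z)
            )
    foci = pd.DataFrame(foci_rows, columns=["nucleus_id", "row", "col", "amplitude", "z_plane"])

    focus_clean = np.full((spec.z_planes, h, w), spec.background, dtype=float)
    for f in foci.itertuples():
        r0, r1 = max(0, int(f.row) - 8), min(h, int(f.row) + 9)
        c0, c1 = max(0, int(f.col) - 8), min(w, int(f.col) + 9)
        sub_r, sub_c = np.mgrid[r0:r1, c0:c1]
        spot = f.amplitude * np.exp(
            -((sub_r - f.row) ** 2 + (sub_c - f.col) ** 2) / (2 * spec.focus_sigma**2)
        )
        focus_clean[f.z_plane, r0:r1, c0:c1] += spot

    dapi_clean = np.where(masks > 0, spec.dapi_foreground, spec.dapi_background).astype(float)

    def _noisify(img: np.ndarray) -> np.ndarray:
        if noise_kind == "gaussian":
            out = img + rng.normal(0.0, noise_scale, size=img.shape)
        elif noise_kind == "poisson":
            out = rng.poisson(np.clip(img, 0, None) / noise_scale).astype(float) * noise_scale
        else:
            raise ValueError(f"unknown noise model {noise_kind!r}")
        return np.clip(out, 0.0, None)

    focus_img = _noisify(focus_clean)
    if spec.z_planes == 1:
        focus_img = focus_img[0]
    dapi_img = _noisify(dapi_clean)

    stack = ImageStack(channels={"dapi": dapi_img, "gH2AX": focus_img})
    return stack, ImageTruth(nuclei=nuclei, foci=foci, masks=masks)


# ---------------------------------------------------------------------------
# junction-read simulation
# ---------------------------------------------------------------------------

@dataclass
class JunctionSimSpec:
    """Planted repair-event mix for an I-SceI reporter amplicon.

    ``category_proportions`` order: (direct, deletion, delins, insertion).
    Deletion sizes and insertion lengths are drawn from the given discrete
    values with equal weight unless weights are supplied; microhomology
    targets apply to simple deletions and are realized by searching deletion
    placements on the reference.
    """

    reference: ReferenceAmplicon
    n_reads: int = 70
    category_proportions: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    deletion_sizes: tuple[int, ...] = (1, 2, 3, 5, 8, 12, 20, 35)
    insertion_lengths: tuple[int, ...] = (1, 2, 3, 5, 8)
    mh_targets: tuple[int, ...] = (0, 0, 1, 1, 2, 3)
    per_base_error: float = 0.0
    max_retries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.category_proportions, dtype=float)
        if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("category proportions must lie in [0,1] and sum to 1")


def make_toy_reference(length: int = 240, cut_position: int | None = None, seed: int = 0) -> ReferenceAmplicon:
    """A synthetic stand-in for the (unpublished) reporter amplicon.

    Random sequence with a few short direct repeats seeded around the cut so
    that non-zero microhomology deletions are realizable.
    """
    rng = _rng(_KEY_REFERENCE, seed)
    cut = cut_position if cut_position is not None else length // 2
    seq = list(rng.choice(list("ACGT"), size=length))
    # plant short repeats straddling the cut to make MH 1-3 reachable
    for offset, k in ((6, 3), (14, 2), (25, 3)):
        left = cut - offset
        right = cut + offset - k
        if 0 <= left and right + k <= length:
            seq[right : right + k] = seq[left : left + k]
    return ReferenceAmplicon(sequence="".join(seq), cut_position=cut, name="synthetic_amplicon")


def _plant_deletion(
    ref: ReferenceAmplicon, size: int, mh_target: int, rng: np.random.Generator, max_retries: int
) -> tuple[int, int] | None:
    """Find a deletion of ``size`` covering the cut with the target MH."""
    cut = ref.cut_position
    starts = np.arange(max(0, cut - size), min(cut, len(ref.sequence) - size) + 1)
    rng.shuffle(starts)
    for a in starts[: max_retries]:
        if microhomology(ref, int(a), int(a) + size) == mh_target:
            return int(a), int(a) + size
    return None


def _random_insert(ref: ReferenceAmplicon, length: int, a: int, b: int, rng: np.random.Generator) -> str:
    """Insertion into deletion [a, b) whose ends cannot extend the anchors.

    The first base must differ from ref[a] (else the left anchor would absorb
    it) and the last base from ref[b-1] (else the right anchor would), so the
    planted junction is recovered verbatim on error-free reads.
    """
    seq = ref.sequence
    while True:
        ins = "".join(rng.choice(list("ACGT"), size=length))
        left_clash = a < len(seq) and ins[0] == seq[a]
        right_clash = b >= 1 and ins[-1] == seq[b - 1]
        if not left_clash and not right_clash:
            return ins


def simulate_junction_reads(spec: JunctionSimSpec):
    """Simulate cloned junction reads; returns (records, truth table).

    Each read applies one planted event at the cut site.  Insertion ends are
    constrained to mismatch the junction-adjacent reference bases so flank
    anchors terminate exactly at the planted junction; deletion intervals are
    chosen to realize the targeted microhomology where the reference allows,
    with resampling up to ``max_retries`` and an error if no target is
    realizable.  Records are ``(read_id, sequence)`` pairs; truth holds every
    planted parameter.
    """
    rng = _rng(_KEY_JUNCTIONS, spec.seed)
    ref = spec.reference
    seq = ref.sequence
    cut = ref.cut_position
    categories = ("direct", "deletion", "delins", "insertion")
    records: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(spec.n_reads):
        cat = categories[rng.choice(4, p=spec.category_proportions)]
        read_id = f"read{i:04d}_{cat}"
        a = b = 0
        ins = ""
        mh = 0
        if cat == "direct":
            read = seq
        elif cat == "deletion":
            placed = None
            for _ in range(spec.max_retries):
                size = int(rng.choice(spec.deletion_sizes))
                mh_t = int(rng.choice(spec.mh_targets))
                placed = _plant_deletion(ref, size, mh_t, rng, spec.max_retries)
                if placed is not None:
                    break
            if placed is None:
                raise ValueError(
                    "could not realize any requested (deletion size, microhomology) on this reference"
                )
            a, b = placed
            mh = microhomology(ref, a, b)
            # canonical leftmost placement for the truth record
            while a > 0 and seq[a - 1] == seq[b - 1]:
                a -= 1
                b -= 1
            read = seq[:a] + seq[b:]
        elif cat == "insertion":
            length = int(rng.choice(spec.insertion_lengths))
            ins = _random_insert(ref, length, cut, cut, rng)
            read = seq[:cut] + ins + seq[cut:]
        else:  # delins
            size = int(rng.choice(spec.deletion_sizes))
            starts = np.arange(max(0, cut - size), min(cut, len(seq) - size) + 1)
            a = int(rng.choice(starts))
            b = a + size
            length = int(rng.choice(spec.insertion_lengths))
            ins = _random_insert(ref, length, a, b, rng)
            read = seq[:a] + ins + seq[b:]
        if spec.per_base_error > 0:
            read = _apply_errors(read, spec.per_base_error, rng)
        records.append((read_id, read))
        truth_rows.append(
            dict(
                read_id=read_id,
                category=cat,
                del_start=a,
                del_end=b,
                deletion_size=b - a,
                inserted_seq=ins,
                microhomology_len=mh,
            )
        )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    bases = "ACGT"
    out = list(read)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[(bases.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, s in records:
            fh.write(f">{rid}\n{s}\n")
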