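"""Synthetic window-view scenes and participant cohorts with ground truth.

The study this package re-implements measured real photographs and real
participants; neither is publicly available, so validation runs on
simulated stand-ins whose generating parameters are known exactly.

Scenes are schematic, not photorealistic: a top sky band (blue gradient
or overcast grey), axis-aligned building facades with window grids
(straight edges), and green foliage carved out of multi-octave value
noise (irregular outline, high fractal dimension).  The extractor
consumes pixel statistics, not semantics, so schematic scenes with
exactly known sky/green/built fractions are the right test bed.

Cohorts emulate the study's bookkeeping: ~110 participants sending in a
handful of window photographs each (truncated negative binomial around
mean 5.58, SD 4.01), subjective ratings generated from planted linear
models on the true scene fractions (the three percentage estimates
forced to sum to 100 by largest-remainder rounding), demographics drawn
from the published sample marginals, STADI item responses realising a
planted negative-affect composite that depends negatively on the
brightness rating, and delay-discounting choice logs produced by
hyperbolic agents (choose delayed iff 100/(1 + k*D) >= offer) run
through the real staircase.  One diverse-sex participant and a
configurable number of missing outcomes are injected to exercise the
analysis-stage exclusion rules.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import hsv2rgb

from . import behavioral
from .behavioral import (
    DELAY_LABELS,
    DELAYS_DAYS,
    DEFAULT_FACETS,
    StaircaseState,
    staircase_step,
)

# ---------------------------------------------------------------------------
# scenes


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth parameters of one synthetic window view."""

    p_sky: float = 0.3
    sky_kind: str = "blue"  # "blue" | "overcast"
    p_green: float = 0.3
    built_density: float = 0.5
    foliage_roughness: float = 0.55
    #: global tone gains emulating per-camera exposure/saturation variation
    sat_gain: float = 1.0
    val_gain: float = 1.0
    width: int = 128
    height: int = 128
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_sky <= 1.0 and 0.0 <= self.p_green <= 1.0):
            raise ValueError("p_sky and p_green must lie in [0, 1]")
        if self.p_sky + self.p_green > 1.0 + 1e-12:
            raise ValueError(
                f"infeasible scene: p_sky + p_green = {self.p_sky + self.p_green} > 1"
            )
        if self.sky_kind not in ("blue", "overcast"):
            raise ValueError("sky_kind must be 'blue' or 'overcast'")


def _value_noise(rng, shape: tuple[int, int], roughness: float, octaves: int = 4):
    """Multi-octave interpolated noise field (midpoint-displacement style)."""
    h, w = shape
    out = np.zeros(shape)
    amp = 1.0
    for o in range(octaves):
        g = 2 ** (o + 2) + 1
        coarse = rng.standard_normal((g, g))
        up = ndimage.zoom(coarse, (h / g, w / g), order=1, grid_mode=True, mode="nearest")
        out += amp * up[:h, :w]
        amp *= roughness
    return out


def generate_scene(spec: SceneSpec):
    """Render a scene; returns ``(image, sky_masked, truth)``.

    ``image`` and ``sky_masked`` are HxWx3 uint8; in the masked
    companion every non-sky pixel is exact black.  ``truth`` holds the
    realized (pixel-counted) sky, green, and built fractions.
    Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    hue = np.zeros((h, w))
    sat = np.zeros((h, w))
    val = np.zeros((h, w))

    sky_rows = int(round(spec.p_sky * h))
    grad = np.linspace(0.0, 1.0, max(sky_rows, 1))[:, None] * np.ones((1, w))
    if sky_rows:
        if spec.sky_kind == "blue":
            hue[:sky_rows] = (215.0 + 10.0 * grad[:sky_rows]) / 360.0
            sat[:sky_rows] = 0.45 - 0.20 * grad[:sky_rows]
            val[:sky_rows] = 0.70 + 0.25 * grad[:sky_rows]
        else:
            hue[:sky_rows] = 220.0 / 360.0
            sat[:sky_rows] = 0.05
            val[:sky_rows] = 0.78 + 0.10 * grad[:sky_rows] + 0.02 * rng.standard_normal(
                (sky_rows, w)
            )

    # built background below the skyline: warm grey facade tone
    ground = slice(sky_rows, h)
    hue[ground] = 30.0 / 360.0
    sat[ground] = 0.10 + 0.04 * rng.random((h - sky_rows, w))
    val[ground] = 0.42 + 0.05 * rng.standard_normal((h - sky_rows, w))

    # buildings: rectangles with window grids (straight-edge content)
    n_buildings = int(round(1 + spec.built_density * 5))
    for _ in range(n_buildings if sky_rows < h else 0):
        bw = rng.integers(w // 8, max(w // 3, w // 8 + 1))
        bh = rng.integers((h - sky_rows) // 3 + 1, max(h - sky_rows, (h - sky_rows) // 3 + 2))
        c0 = int(rng.integers(0, max(w - bw, 1)))
        r0 = h - bh
        shade = 0.30 + 0.25 * rng.random()
        val[r0:h, c0 : c0 + bw] = shade
        sat[r0:h, c0 : c0 + bw] = 0.08
        # window grid: bright rectangles every few pixels
        win = 0.75 + 0.15 * rng.random()
        pitch_r = int(rng.integers(6, 12))
        pitch_c = int(rng.integers(6, 12))
        for rr in range(r0 + 2, h - 3, pitch_r):
            for cc in range(c0 + 2, c0 + bw - 3, pitch_c):
                val[rr : rr + max(pitch_r // 2, 2), cc : cc + max(pitch_c // 2, 2)] = win

    # foliage: threshold a fractal noise field over the non-sky region
    n_green_target = int(round(spec.p_green * h * w))
    green_mask = np.zeros((h, w), bool)
    if n_green_target > 0 and sky_rows < h:
        noise = _value_noise(rng, (h, w), spec.foliage_roughness)
        candidates = noise[ground].ravel()
        n_avail = candidates.size
        n_take = min(n_green_target, n_avail)
        cut = np.partition(candidates, n_avail - n_take)[n_avail - n_take]
        sel = noise >= cut
        sel[:sky_rows] = False
        # exact count: drop surplus ties deterministically (row-major order)
        surplus = int(sel.sum()) - n_take
        if surplus > 0:
            tie_idx = np.flatnonzero(sel.ravel())
            sel.ravel()[tie_idx[-surplus:]] = False
        green_mask = sel
        texture = rng.random((h, w))
        hue[green_mask] = (95.0 + 40.0 * texture[green_mask]) / 360.0
        sat[green_mask] = 0.55 + 0.25 * texture[green_mask]
        val[green_mask] = 0.25 + 0.40 * rng.random((h, w))[green_mask]

    hsv = np.stack(
        [
            hue % 1.0,
            np.clip(sat * spec.sat_gain, 0, 1),
            np.clip(val * spec.val_gain, 0.03, 1),
        ],
        axis=-1,
    )
    img = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)

    masked = img.copy()
    masked[sky_rows:] = 0

    truth = {
        "sky_fraction": sky_rows * w / (h * w),
        "green_fraction": float(green_mask.sum()) / (h * w),
        "built_fraction": 1.0 - sky_rows * w / (h * w) - float(green_mask.sum()) / (h * w),
        "sky_kind": spec.sky_kind,
        "built_density": spec.built_density,
        "seed": spec.seed,
    }
    return img, masked, truth


# ---------------------------------------------------------------------------
# ratings


@dataclass(frozen=True)
class RatingModel:
    """Planted linear models mapping true scene fractions to ratings.

    The three percentage estimates are drawn on the simplex
    (logistic-normal noise around the true fractions) and rounded to
    integers summing to exactly 100.  The 0-100 scales are planted
    linear responses with Gaussian noise, clipped to range.
    """

    simplex_noise_sd: float = 0.35  # on the log-ratio scale
    quality_coef: tuple[float, float, float] = (25.0, 45.0, 55.0)  # c0, green, sky
    quality_noise_sd: float = 15.0
    brightness_coef: tuple[float, float] = (45.0, 45.0)  # b0, sky
    brightness_noise_sd: float = 12.0
    green_vis_coef: tuple[float, float] = (8.0, 110.0)  # g0, green
    green_vis_noise_sd: float = 10.0
    long_view_coef: tuple[float, float, float] = (35.0, 55.0, -25.0)  # l0, sky, built
    long_view_noise_sd: float = 15.0


def largest_remainder_round(values, total: int = 100) -> np.ndarray:
    """Round nonnegative values to integers that sum exactly to ``total``.

    Floors each value, then hands the remaining units to the largest
    fractional parts (ties to the earliest index).
    """
    values = np.asarray(values, float)
    scaled = values * (total / values.sum())
    floors = np.floor(scaled).astype(int)
    remainder = int(total - floors.sum())
    frac = scaled - floors
    order = np.argsort(-frac, kind="stable")
    floors[order[:remainder]] += 1
    return floors


def generate_ratings(truth: dict, model: RatingModel, rng) -> dict:
    """Subjective ratings for one participant from averaged scene truth."""
    fractions = np.array(
        [truth["green_fraction"], truth["built_fraction"], truth["sky_fraction"]]
    )
    eps = 1e-6
    z = np.log(fractions + eps) + rng.normal(0.0, model.simplex_noise_sd, 3)
    wts = np.exp(z - z.max())
    wts /= wts.sum()
    pct = largest_remainder_round(wts, 100)
    g, b, s = fractions

    def planted(coefs, xs, sd):
        mu = coefs[0] + sum(c * x for c, x in zip(coefs[1:], xs))
        return float(np.clip(mu + rng.normal(0.0, sd), 0.0, 100.0))

    return {
        "pct_nature": int(pct[0]),
        "pct_manmade": int(pct[1]),
        "pct_sky": int(pct[2]),
        "quality": planted(model.quality_coef, (g, s), model.quality_noise_sd),
        "brightness_rating": planted(model.brightness_coef, (s,), model.brightness_noise_sd),
        "green_visibility": planted(model.green_vis_coef, (g,), model.green_vis_noise_sd),
        "vegetation_rooms": int(rng.poisson(1.0 + 6.0 * g)),
        "long_distance_view": planted(model.long_view_coef, (s, b), model.long_view_noise_sd),
    }


# ---------------------------------------------------------------------------
# outcomes


@dataclass(frozen=True)
class OutcomeModel:
    """Planted outcome-generating parameters.

    State negative affect depends negatively on the brightness rating
    (brighter homes, lower negative affect); the delay-discounting AUC
    is driven entirely by each agent's hyperbolic discount rate k,
    drawn log-normally around a median of 0.01 per day.
    """

    na_intercept: float = 58.0
    na_brightness_coef: float = -0.12
    na_noise_sd: float = 5.5
    stadi_item_noise_sd: float = 0.8
    k_log10_mean: float = -2.0
    k_log10_sd: float = 0.8


def stadi_items_for_composite(
    target: int, rng, item_noise_sd: float = 0.0, facets=DEFAULT_FACETS
) -> np.ndarray:
    """Sample 20 stored item responses whose scored sum is ``target``.

    Items are drawn around the per-item mean with optional noise, then
    nudged one point at a time until the scored composite matches
    exactly.  Euthymia items are returned un-reversed (as a respondent
    would mark them).
    """
    if not (20 <= target <= 80):
        raise ValueError(f"composite target {target} outside [20, 80]")
    base = target / 20.0
    scored = np.clip(
        np.rint(base + rng.normal(0.0, item_noise_sd, 20)), 1, 4
    ).astype(int)
    diff = target - int(scored.sum())
    while diff != 0:
        step = 1 if diff > 0 else -1
        adjustable = np.flatnonzero(
            (scored < 4) if diff > 0 else (scored > 1)
        )
        idx = adjustable[rng.integers(len(adjustable))]
        scored[idx] += step
        diff -= step
    reverse = np.array([f == "euthymia" for f in facets])
    return np.where(reverse, 5 - scored, scored)


def hyperbolic_choices(k: float, rng=None) -> pd.DataFrame:
    """Choice log of a hyperbolic agent over all 7 staircase blocks.

    The agent values EUR 100 at delay D as 100 / (1 + k*D) and chooses
    the delayed reward iff that value is at least the immediate offer
    (ties break toward delayed).  Block order is randomized when an rng
    is given; scoring is order-invariant.
    """
    block_order = np.arange(len(DELAY_LABELS))
    if rng is not None:
        block_order = rng.permutation(block_order)
    rows = []
    for bi in block_order:
        label, delay = DELAY_LABELS[bi], DELAYS_DAYS[bi]
        sv = behavioral.DELAYED_AMOUNT / (1.0 + k * delay)
        state = StaircaseState(delay_days=delay)
        for _ in range(behavioral.TRIALS_PER_BLOCK):
            choice = "delayed" if sv >= state.immediate_offer else "immediate"
            rows.append(
                {
                    "delay_label": label,
                    "trial_index": state.trial_index,
                    "immediate_offer": state.immediate_offer,
                    "choice": choice,
                }
            )
            state = staircase_step(state, choice)
    return pd.DataFrame(rows)


def generate_outcomes(ratings: dict, model: OutcomeModel, rng):
    """Planted outcomes for one participant.

    Returns ``(stadi_items, choices, truth)`` where truth records the
    planted composite and discount rate.
    """
    na = model.na_intercept + model.na_brightness_coef * ratings[
        "brightness_rating"
    ] + rng.normal(0.0, model.na_noise_sd)
    composite = int(np.clip(np.rint(na), 20, 80))
    items = stadi_items_for_composite(
        composite, rng, item_noise_sd=model.stadi_item_noise_sd
    )
    k = float(10.0 ** rng.normal(model.k_log10_mean, model.k_log10_sd))
    choices = hyperbolic_choices(k, rng)
    return items, choices, {"na_composite": composite, "k": k}


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Study-level simulation parameters.

    Defaults follow the published sample: 110 participants, image count
    with mean 5.58 and SD 4.01 (negative binomial truncated at 1),
    demographic marginals from the sample table, one diverse-sex
    participant, and 2 / 1 injected missing outcomes for negative
    affect / AUC.
    """

    n_participants: int = 110
    image_count_mean: float = 5.58
    image_count_sd: float = 4.01
    image_size: tuple[int, int] = (128, 128)
    rating_model: RatingModel = field(default_factory=RatingModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    overcast_prob: float = 0.4
    inject_diverse: bool = True
    n_missing_negative_affect: int = 2
    n_missing_auc: int = 1
    seed: int = 0


#: published income-band frequencies (ordinal 1..7) out of N = 110
_INCOME_PROBS = np.array([39, 16, 11, 24, 10, 5, 5]) / 110.0
#: male / female frequencies among the 109 binary-sex participants
_SEX_PROBS = np.array([28, 81]) / 109.0


@dataclass
class ParticipantRecord:
    """Everything simulated for one participant."""

    participant_id: str
    images: list
    masks: list
    image_truths: list
    truth: dict  # averaged scene fractions + planted outcome truth
    ratings: dict
    demographics: dict
    stadi_items: np.ndarray | None  # None = missing outcome
    choices: pd.DataFrame | None


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list

    def ratings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"participant_id": p.participant_id, **p.ratings} for p in self.participants]
        )

    def demographics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"participant_id": p.participant_id, **p.demographics}
                for p in self.participants
            ]
        )

    def stadi_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            if p.stadi_items is None:
                continue
            row = {"participant_id": p.participant_id}
            row.update({f"item_{i+1}": int(v) for i, v in enumerate(p.stadi_items)})
            rows.append(row)
        return pd.DataFrame(rows)

    def choices_frame(self) -> pd.DataFrame:
        frames = []
        for p in self.participants:
            if p.choices is None:
                continue
            f = p.choices.copy()
            f.insert(0, "participant_id", p.participant_id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def ground_truth(self) -> dict:
        return {
            "spec": _spec_to_jsonable(self.spec),
            "participants": {
                p.participant_id: p.truth for p in self.participants
            },
        }


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["image_size"] = list(d["image_size"])
    return d


def _sample_image_count(rng, mean: float, sd: float) -> int:
    var = sd * sd
    if var <= mean:  # degenerate: fall back to Poisson
        return max(1, int(rng.poisson(mean)))
    p = mean / var
    r = mean * mean / (var - mean)
    return max(1, int(rng.negative_binomial(r, p)))


def simulate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Simulate a full cohort in memory.

    Per participant: scene parameters for their home are drawn once and
    jittered per window image; ratings respond to the average realized
    fractions over their images; outcomes follow the planted models.
    Deterministic for a fixed spec (including its seed).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    participants = []

    diverse_idx = int(rng.integers(n)) if spec.inject_diverse else -1
    eligible = [i for i in range(n) if i != diverse_idx]
    n_miss = spec.n_missing_negative_affect + spec.n_missing_auc
    miss = rng.choice(len(eligible), size=min(n_miss, len(eligible)), replace=False)
    miss_na = {eligible[i] for i in miss[: spec.n_missing_negative_affect]}
    miss_auc = {eligible[i] for i in miss[spec.n_missing_negative_affect :]}

    h, w = spec.image_size
    for i in range(n):
        pid = f"p{i+1:03d}"
        p_sky = float(rng.uniform(0.05, 0.45))
        p_green = float(rng.uniform(0.02, min(0.6, 1.0 - p_sky - 0.15)))
        built = float(rng.uniform(0.2, 0.9))
        sky_kind = "overcast" if rng.random() < spec.overcast_prob else "blue"
        # one camera per participant: exposure and saturation tone vary
        # between homes much more than between windows of one home
        sat_gain = float(rng.uniform(0.6, 1.4))
        val_gain = float(rng.uniform(0.85, 1.15))
        n_images = _sample_image_count(
            rng, spec.image_count_mean, spec.image_count_sd
        )

        images, masks, truths = [], [], []
        for j in range(n_images):
            ps = float(np.clip(p_sky + rng.normal(0, 0.05), 0.0, 0.6))
            pg = float(np.clip(p_green + rng.normal(0, 0.05), 0.0, 1.0 - ps))
            scene = SceneSpec(
                p_sky=ps,
                sky_kind=sky_kind,
                p_green=pg,
                built_density=built,
                sat_gain=sat_gain,
                val_gain=val_gain,
                width=w,
                height=h,
                seed=int(rng.integers(2**31)),
            )
            img, masked, truth = generate_scene(scene)
            images.append(img)
            masks.append(masked)
            truths.append(truth)

        avg_truth = {
            key: float(np.mean([t[key] for t in truths]))
            for key in ("sky_fraction", "green_fraction", "built_fraction")
        }
        ratings = generate_ratings(avg_truth, spec.rating_model, rng)
        items, choices, outcome_truth = generate_outcomes(
            ratings, spec.outcome_model, rng
        )
        if i in miss_na:
            items = None
        if i in miss_auc:
            choices = None

        sex = (
            "diverse"
            if i == diverse_idx
            else ("male", "female")[int(rng.random() < _SEX_PROBS[1])]
        )
        demographics = {
            "age": float(np.clip(np.rint(rng.normal(26.8, 7.99)), 18, 65)),
            "sex": sex,
            "income": int(rng.choice(7, p=_INCOME_PROBS) + 1),
            "living_space": float(np.rint(np.clip(rng.lognormal(np.log(70.0), 0.5), 15, 600))),
            "time_home_pre": float(np.clip(np.rint(rng.normal(14.0, 4.0)), 2, 24)),
            "time_home_covid": float(np.clip(np.rint(rng.normal(20.0, 3.0)), 4, 24)),
            "image_count": n_images,
        }
        participants.append(
            ParticipantRecord(
                participant_id=pid,
                images=images,
                masks=masks,
                image_truths=truths,
                truth={**avg_truth, **outcome_truth},
                ratings=ratings,
                demographics=demographics,
                stadi_items=items,
                choices=choices,
            )
        )
    return Cohort(spec=spec, participants=participants)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Serialize a cohort to the on-disk dataset layout.

    ``<out>/<pid>/window_<j>.png`` (+ ``_skymask.png``), plus
    ``ratings.csv``, ``demographics.csv``, ``stadi_items.csv``,
    ``choices.csv`` and ``ground_truth.json`` at the top level.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort.participants:
        pdir = out / p.participant_id
        pdir.mkdir(exist_ok=True)
        for j, (img, mask) in enumerate(zip(p.images, p.masks), start=1):
            iio.imwrite(pdir / f"window_{j}.png", img)
            iio.imwrite(pdir / f"window_{j}_skymask.png", mask)
    cohort.ratings_frame().to_csv(out / "ratings.csv", index=False)
    cohort.demographics_frame().to_csv(out / "demographics.csv", index=False)
    cohort.stadi_frame().to_csv(out / "stadi_items.csv", index=False)
    cohort.choices_frame().to_csv(out / "choices.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth(), fh, indent=1)
    return out
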