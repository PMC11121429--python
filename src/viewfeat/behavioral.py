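"""Behavioral outcome scoring: state negative affect and delay discounting.

Two outcomes are scored here.  The first is a state negative-affect
composite from the 20 state items of the State-Trait Anxiety-Depression
Inventory (STADI): anxiety (emotionality + worry facets) and depression
(euthymia + dysthymia facets) items on a 1-4 scale, euthymia reversed,
summed to a composite in [20, 80].

The second is impulsive decision-making from an adaptive delay-discounting
task: for each of seven delays the participant makes six choices between
an immediate amount (starting at EUR 50) and EUR 100 delayed, with the
immediate offer titrated up or down by half the previous step after each
choice.  The limit of this titration is the indifference point for that
delay; the normalized trapezoidal area under the seven-point
indifference curve (AUC) summarises discounting, larger AUC meaning less
impulsive decision-making.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: facet of each of the 20 state items, in instrument order
DEFAULT_FACETS = (
    ("emotionality",) * 5 + ("worry",) * 5 + ("euthymia",) * 5 + ("dysthymia",) * 5
)

#: task delays in days: 6 h, 1 d, 1 wk, 1 mo, 3 mo, 1 yr, 5 yr
DELAYS_DAYS = (0.25, 1.0, 7.0, 30.0, 91.0, 365.0, 1825.0)

#: labels matching DELAYS_DAYS, used in choice logs
DELAY_LABELS = ("6h", "1d", "1w", "1m", "3m", "1y", "5y")

DELAYED_AMOUNT = 100.0
INITIAL_OFFER = 50.0
TRIALS_PER_BLOCK = 6


def score_stadi(responses, facets=DEFAULT_FACETS) -> int:
    """State negative-affect composite from 20 item responses in {1..4}.

    Euthymia items are reverse-scored (r -> 5 - r), then all 20 items
    are summed; the composite ranges from 20 to 80, higher = more
    negative affect.
    """
    resp = np.asarray(responses)
    if resp.shape != (20,):
        raise ValueError(f"expected exactly 20 item responses, got {resp.shape}")
    if np.isnan(resp.astype(float)).any():
        raise ValueError("missing item response")
    resp = resp.astype(int)
    if ((resp < 1) | (resp > 4)).any():
        raise ValueError("item responses must be integers in 1..4")
    if len(facets) != 20:
        raise ValueError("expected 20 facet labels")
    reverse = np.array([f == "euthymia" for f in facets])
    if reverse.sum() != 5:
        raise ValueError("expected exactly 5 euthymia items")
    scored = np.where(reverse, 5 - resp, resp)
    return int(scored.sum())


@dataclass(frozen=True)
class StaircaseState:
    """One block of the titration staircase at a given delay."""

    delay_days: float
    trial_index: int = 1  # 1-based; the trial about to be answered
    immediate_offer: float = INITIAL_OFFER
    delayed_amount: float = DELAYED_AMOUNT

    @property
    def adjustment(self) -> float:
        """Step applied after the current trial: 100 / 2**(t+1)."""
        return self.delayed_amount / 2 ** (self.trial_index + 1)


def staircase_step(state: StaircaseState, choice: str) -> StaircaseState:
    """Apply one choice and return the next staircase state.

    Choosing the immediate reward lowers the next offer by the current
    adjustment (the delayed option must be made relatively more
    attractive); choosing the delayed reward raises it.  The step
    halves each trial: +/-25, +/-12.5, ..., +/-1.5625 after trial 6.
    """
    if choice not in ("immediate", "delayed"):
        raise ValueError(f"choice must be 'immediate' or 'delayed', got {choice!r}")
    if state.trial_index > TRIALS_PER_BLOCK:
        raise ValueError(
            f"block complete: no choices after trial {TRIALS_PER_BLOCK}"
        )
    delta = state.adjustment
    offer = state.immediate_offer + (delta if choice == "delayed" else -delta)
    return replace(state, trial_index=state.trial_index + 1, immediate_offer=offer)


def indifference_point(choices) -> float:
    """Indifference point (EUR) implied by one block's six choices.

    Defined as the offer a hypothetical seventh trial would present:
    the titration's limit, final offer +/- 100/2**7.
    """
    choices = list(choices)
    if len(choices) != TRIALS_PER_BLOCK:
        raise ValueError(
            f"expected exactly {TRIALS_PER_BLOCK} choices, got {len(choices)}"
        )
    state = StaircaseState(delay_days=0.0)
    for choice in choices:
        state = staircase_step(state, choice)
    return state.immediate_offer


@dataclass(frozen=True)
class IndifferenceCurve:
    """Seven (delay, indifference point) pairs for one participant."""

    delays_days: tuple[float, ...]
    points_eur: tuple[float, ...]

    def __post_init__(self):
        if len(self.delays_days) != 7 or len(self.points_eur) != 7:
            raise ValueError("expected exactly 7 (delay, indifference point) pairs")
        if any(not (0.0 <= p <= DELAYED_AMOUNT) for p in self.points_eur):
            raise ValueError("indifference points must lie in [0, 100] EUR")


def auc(curve: IndifferenceCurve, anchor_at_zero: bool = True) -> float:
    """Normalized area under the indifference curve, in [0, 1].

    Delays are scaled by the maximum delay and points by the delayed
    amount; the trapezoidal area is accumulated over consecutive
    points.  By default the curve is anchored at (0, 1) — the delayed
    reward is worth its face value at zero delay; ``anchor_at_zero=False``
    integrates from the first delay instead.
    """
    order = np.argsort(curve.delays_days)
    x = np.asarray(curve.delays_days, float)[order] / max(curve.delays_days)
    y = np.asarray(curve.points_eur, float)[order] / DELAYED_AMOUNT
    if anchor_at_zero:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[1.0], y])
    return float(np.trapezoid(y, x))


def score_choice_log(log: pd.DataFrame) -> pd.DataFrame:
    """Score a staircase choice log into per-participant curves and AUC.

    ``log`` columns: participant_id, delay_label, trial_index, choice
    (an ``immediate_offer`` column, if present, is validated against the
    replayed staircase).  Returns one row per participant with the seven
    indifference points (columns ``ip_<label>``) and ``auc``.
    """
    required = {"participant_id", "delay_label", "trial_index", "choice"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"choice log missing columns: {sorted(missing)}")
    rows = []
    for pid, part in log.groupby("participant_id", sort=True):
        points = {}
        for label, block in part.groupby("delay_label"):
            if label not in DELAY_LABELS:
                raise ValueError(f"unknown delay label {label!r}")
            block = block.sort_values("trial_index")
            if list(block["trial_index"]) != list(range(1, TRIALS_PER_BLOCK + 1)):
                raise ValueError(
                    f"participant {pid} delay {label}: expected trials 1..6"
                )
            if "immediate_offer" in block.columns:
                state = StaircaseState(delay_days=0.0)
                for offer, choice in zip(block["immediate_offer"], block["choice"]):
                    if abs(state.immediate_offer - float(offer)) > 1e-9:
                        raise ValueError(
                            f"participant {pid} delay {label}: logged offer "
                            f"{offer} != staircase offer {state.immediate_offer}"
                        )
                    state = staircase_step(state, choice)
            points[label] = indifference_point(block["choice"])
        if set(points) != set(DELAY_LABELS):
            raise ValueError(
                f"participant {pid}: expected all 7 delay blocks, got {sorted(points)}"
            )
        curve = IndifferenceCurve(
            delays_days=DELAYS_DAYS,
            points_eur=tuple(points[lab] for lab in DELAY_LABELS),
        )
        row = {"participant_id": pid, "auc": auc(curve)}
        row.update({f"ip_{lab}": points[lab] for lab in DELAY_LABELS})
        rows.append(row)
    return pd.DataFrame(rows)


def score_stadi_table(items: pd.DataFrame, facets=DEFAULT_FACETS) -> pd.DataFrame:
    """Score a table of STADI state items.

    ``items`` columns: participant_id plus item_1..item_20 (stored
    un-reversed).  Rows with any missing item yield NaN (listwise
    exclusion is handled downstream).
    """
    cols = [f"item_{i}" for i in range(1, 21)]
    missing = set(cols) - set(items.columns)
    if missing:
        raise ValueError(f"STADI table missing columns: {sorted(missing)}")
    out = []
    for _, row in items.iterrows():
        vals = row[cols].to_numpy(dtype=float)
        if np.isnan(vals).any():
            score: float = float("nan")
        else:
            score = score_stadi(vals.astype(int), facets)
        out.append({"participant_id": row["participant_id"], "negative_affect": score})
    return pd.DataFrame(out)
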