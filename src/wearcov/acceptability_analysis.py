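"""Likert and multiple-choice acceptability analysis.

The field questionnaire carries 17 five-point Likert items in three
categories -- acceptance of the wearable, acceptance of wearing two
wearables at once, and technical feasibility (answered by the field
worker) -- plus multiple-choice and open-ended questions.  Positive
agreement for an item is the share of responses in the top two
categories after reversing negatively worded items (r -> 6 - r), the
standard reverse-coding convention.

Percentages are always emitted next to their denominator: the printed
bases in feasibility reports are notoriously inconsistent, so the
denominator policy (respondents / participants / questionnaires) is an
explicit argument, never an implicit choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import age_group_column

logger = logging.getLogger(__name__)

CATEGORIES = ("acceptance_wearable", "acceptance_two_wearables", "technical_feasibility")


@dataclass(frozen=True)
class LikertItem:
    item_id: str
    text: str
    category: str
    polarity: str = "positive"
    respondent: str = "participant"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be positive/negative")


@dataclass(frozen=True)
class MCQuestion:
    question_id: str
    text: str
    options: tuple[str, ...]
    multi_select: bool = False
    default_probs: tuple[float, ...] = ()


# The published item wordings live in supplementary material; the default
# catalog reproduces the documented structure (17 items, three categories,
# polarity flags, field-worker respondents for technical feasibility) with
# placeholder texts.  default_agreement drives the synthetic generator.
_DEFAULT_ITEMS = [
    # (item_id, category, polarity, respondent, default_agreement, text)
    ("aw1", "acceptance_wearable", "positive", "participant", 0.99,
     "I felt comfortable wearing the wristband"),
    ("aw2", "acceptance_wearable", "positive", "participant", 0.98,
     "Wearing the wristband was easy"),
    ("aw3", "acceptance_wearable", "negative", "participant", 0.97,
     "The wristband disturbed my daily activities"),
    ("aw4", "acceptance_wearable", "positive", "participant", 0.96,
     "I would wear the wristband again"),
    ("aw5", "acceptance_wearable", "negative", "participant", 0.95,
     "The wristband affected my sleep"),
    ("aw6", "acceptance_wearable", "positive", "participant", 0.97,
     "I liked the look of the wristband"),
    ("aw7", "acceptance_wearable", "positive", "participant", 0.94,
     "My family accepted the wristband"),
    ("aw8", "acceptance_wearable", "positive", "participant", 1.00,
     "I was willing to wear the device for the whole cycle"),
    ("tw1", "acceptance_two_wearables", "positive", "participant", 0.97,
     "Wearing both devices at once was acceptable"),
    ("tw2", "acceptance_two_wearables", "negative", "participant", 0.96,
     "The thermometer patch was uncomfortable at night"),
    ("tw3", "acceptance_two_wearables", "positive", "participant", 0.95,
     "Attaching the patch each night was easy"),
    ("tw4", "acceptance_two_wearables", "positive", "participant", 0.98,
     "I would wear both devices again"),
    ("tf1", "technical_feasibility", "positive", "field_worker", 0.87,
     "Synchronizing the devices with the tablet was straightforward"),
    ("tf2", "technical_feasibility", "negative", "field_worker", 0.88,
     "The Bluetooth connection failed frequently"),
    ("tf3", "technical_feasibility", "negative", "field_worker", 0.89,
     "Managing the data on the tablet was difficult"),
    ("tf4", "technical_feasibility", "positive", "field_worker", 0.95,
     "The wearable application was easy to use"),
    ("tf5", "technical_feasibility", "positive", "field_worker", 0.93,
     "Charging the devices in the field was manageable"),
]


def default_likert_catalog() -> pd.DataFrame:
    """17-item default catalog as a DataFrame."""
    return pd.DataFrame(
        [{"item_id": i, "category": c, "polarity": p, "respondent": r,
          "default_agreement": a, "text": t}
         for i, c, p, r, a, t in _DEFAULT_ITEMS])


def default_mc_catalog() -> list[MCQuestion]:
    """Multiple-choice questions loosely following the published tables
    (general experience, sleep effect, challenges, removal)."""
    return [
        MCQuestion("experience", "What did you experience when wearing the wearable?",
                   ("not_disturbed", "forgot_wearing", "sometimes_difficult",
                    "needed_time", "limited_movement", "removed", "transpiration"),
                   multi_select=True,
                   default_probs=(0.83, 0.35, 0.07, 0.05, 0.02, 0.01, 0.01)),
        MCQuestion("sleep_effect", "Did wearing the wearables affect your sleep?",
                   ("no", "yes"), default_probs=(0.95, 0.05)),
        MCQuestion("challenges", "Did you experience challenges this week?",
                   ("no", "yes"), default_probs=(0.95, 0.05)),
        MCQuestion("removed_week", "Did you remove the wearable/s this week?",
                   ("no", "yes"), default_probs=(0.96, 0.04)),
    ]


def percent(count: int, denominator: int) -> float:
    """Unrounded percentage of an explicit denominator."""
    if denominator <= 0:
        return float("nan")
    return 100.0 * count / denominator


def percent_display(count: int, denominator: int) -> str:
    """Whole-percent display string (half-up rounding); internal values
    stay unrounded."""
    if denominator <= 0:
        return ""
    return f"{np.floor(percent(count, denominator) + 0.5):.0f}%"


def reverse_scores(responses: pd.DataFrame, catalog: pd.DataFrame) -> pd.Series:
    """Polarity-adjusted scores: r for positive items, 6 - r for negative
    (an involution: applying it twice restores the raw responses)."""
    polarity = responses["item_id"].map(
        catalog.set_index("item_id")["polarity"])
    return responses["response"].where(polarity == "positive",
                                       6 - responses["response"])


def positive_agreement(responses: pd.DataFrame, catalog: pd.DataFrame,
                       per_participant: bool = False) -> pd.DataFrame:
    """Per-item positive agreement (share of polarity-adjusted responses
    in {4, 5}) and the number of scored responses.

    Responses outside 1..5 or for unknown items are rejected with a log
    line.  With ``per_participant`` agreement is first averaged within
    each participant, then across participants.
    """
    df = responses.copy()
    known = df["item_id"].isin(catalog["item_id"])
    valid = df["response"].isin([1, 2, 3, 4, 5])
    n_bad = int((~known | ~valid).sum())
    if n_bad:
        logger.warning("rejected %d responses (unknown item or response outside 1-5)",
                       n_bad)
    df = df[known & valid]
    df = df.assign(score=reverse_scores(df, catalog), agree=lambda d: d["score"] >= 4)
    if per_participant:
        per = df.groupby(["item_id", "participant_id"])["agree"].mean()
        agg = per.groupby("item_id").agg(agreement="mean", n="size")
    else:
        agg = df.groupby("item_id")["agree"].agg(agreement="mean", n="size")
    out = catalog[["item_id", "category", "polarity", "respondent"]].merge(
        agg.reset_index(), on="item_id", how="inner")
    return out


def category_summary(item_agreements: pd.DataFrame, catalog: pd.DataFrame,
                     threshold: float = 0.9) -> pd.DataFrame:
    """Mean/min/max agreement per category plus an overall row with the
    count of items at or above the threshold."""
    if item_agreements.empty:
        raise ValueError("need at least one item agreement")
    df = item_agreements
    if "category" not in df.columns:
        df = df.merge(catalog[["item_id", "category"]], on="item_id")
    per_cat = df.groupby("category", as_index=False)["agreement"].agg(
        mean_agreement="mean", min_agreement="min", max_agreement="max",
        n_items="size")
    per_cat["n_at_threshold"] = [
        int((df.loc[df["category"] == c, "agreement"] >= threshold).sum())
        for c in per_cat["category"]]
    overall = pd.DataFrame([{
        "category": "overall",
        "mean_agreement": df["agreement"].mean(),
        "min_agreement": df["agreement"].min(),
        "max_agreement": df["agreement"].max(),
        "n_items": len(df),
        "n_at_threshold": int((df["agreement"] >= threshold).sum()),
    }])
    return pd.concat([per_cat, overall], ignore_index=True)


def tabulate_mc(responses: pd.DataFrame, catalog: list[MCQuestion],
                denominator_policy: str = "respondents",
                roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Option counts and percentages with an explicit denominator.

    ``respondents``: participant-visit pairs that answered the question;
    ``participants``: distinct participants that answered (or the roster
    size, if a roster is given); ``questionnaires``: all participant-visit
    pairs in the input.  Multi-select options may sum above 100%.  Unknown
    option codes are rejected with a log line.
    """
    if denominator_policy not in ("respondents", "participants", "questionnaires"):
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    rows = []
    n_quest = len(responses[["participant_id", "visit_index"]].drop_duplicates())
    for q in catalog:
        sub = responses[responses["question_id"] == q.question_id]
        known = sub["option"].isin(q.options)
        if (~known).any():
            logger.warning("question %s: rejected %d unknown option codes",
                           q.question_id, int((~known).sum()))
            sub = sub[known]
        if denominator_policy == "respondents":
            den = len(sub[["participant_id", "visit_index"]].drop_duplicates())
        elif denominator_policy == "participants":
            den = (len(roster) if roster is not None
                   else sub["participant_id"].nunique())
        else:
            den = n_quest
        counts = sub.groupby("option").size()
        for opt in q.options:
            n = int(counts.get(opt, 0))
            rows.append({
                "question_id": q.question_id, "option": opt, "count": n,
                "denominator": den,
                "percentage": round(percent(n, den), 1) if den else np.nan,
                "percentage_display": percent_display(n, den),
            })
    return pd.DataFrame(rows)


def subgroup_table(data: pd.DataFrame, roster: pd.DataFrame,
                   keys: list[str], catalog: pd.DataFrame | None = None,
                   value_column: str = "coverage") -> pd.DataFrame:
    """Recompute a metric within subgroups of sex / age group / arm / cycle.

    With a Likert ``catalog``, ``data`` is a response table and the metric
    is pooled positive agreement; otherwise ``data`` must carry
    ``participant_id`` and ``value_column`` (e.g. participant coverage)
    and the metric is its mean.  Emits group, level, metric, n.
    """
    allowed = {"sex", "age_group", "arm", "cycle"}
    bad = set(keys) - allowed
    if bad:
        raise ValueError(f"unknown subgroup keys {sorted(bad)}")
    meta = roster[["participant_id", "sex", "arm", "cycle"]].copy()
    meta["age_group"] = age_group_column(roster)
    df = data.merge(meta, on="participant_id", how="left")
    rows = []
    for key in keys:
        for level, sub in df.groupby(key):
            if catalog is not None:
                agg = positive_agreement(sub, catalog)
                metric = float((agg["agreement"] * agg["n"]).sum() / agg["n"].sum())
                n = int(agg["n"].sum())
            else:
                metric = float(sub[value_column].mean())
                n = int(len(sub))
            rows.append({"group": key, "level": str(level), "metric": metric, "n": n})
    return pd.DataFrame(rows)
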