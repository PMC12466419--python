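"""ASE category assignment from the family's log2 fold-change vector.

Every gene's expression is summarized per individual as a log2FC against
the father.  Each individual gets a state: H (high, log2FC >= 0.8),
M (moderate, |log2FC| <= 0.4) or L (low, log2FC <= -0.8); values in the
gap zones (0.4, 0.8) and (-0.8, -0.4) are UNASSIGNED.  Categories are
written mother-first (H_L = mother high, father low).  Because the
father is the baseline his log2FC is identically zero, so the category's
second letter is fixed by construction.

The five observable categories and their rules, evaluated in a fixed
order on the mother's value and the eight offspring values:

* H_L  - mother > 1; every offspring within [-0.2, mother + 0.2].
* L_H  - mirror: mother < -1; every offspring within [mother - 0.2, 0.2].
* H_M or M_L - mother >= 0.8; every offspring either >= 0.8 (tracking
  the mother) or inside [-0.4, 0.4] (tracking the father); both groups
  non-empty; at least one offspring > 1.
* L_M or M_H - mother <= -0.8; offspring <= -0.8 or inside [-0.4, 0.4];
  both groups non-empty; at least one offspring <= -1.
* M_M  - mother inside [-0.4, 0.4]; every offspring has a defined state;
  at least two distinct states among offspring; at least one offspring
  with |log2FC| >= 1.

The mixture of strict and non-strict inequalities follows the original
rule set verbatim per clause.  In the default "strict" mode an offspring
in a gap zone blocks the group-based categories; "lenient" mode snaps
gap-zone values to the nearest band edge before evaluating group
membership, trading precision for recall under measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np

from famase.core import ConfigurationError, ExpressionState, FamilyDesign


@dataclass(frozen=True)
class Thresholds:
    """Log2FC thresholds anchoring the H/M/L bands.

    strong: |log2FC| anchor for the H_L / L_H parents and the "at least
    one extreme offspring" clauses.  group_hi: boundary of the H (and -L)
    band.  medium_halfwidth: halfwidth of the M band around zero.
    hl_slack: slack added around the [0, mother] span for H_L / L_H
    offspring.
    """

    strong: float = 1.0
    group_hi: float = 0.8
    medium_halfwidth: float = 0.4
    hl_slack: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.medium_halfwidth < self.group_hi <= self.strong):
            raise ConfigurationError(
                "need 0 < medium_halfwidth < group_hi <= strong"
            )
        if self.hl_slack <= 0:
            raise ConfigurationError("hl_slack must be positive")

    @classmethod
    def from_quartiles(
        cls, log2fc_values, strong: float = 1.0, hl_slack: float = 0.2
    ) -> "Thresholds":
        """Data-driven alternative: the H/L band boundary from the 1st and
        3rd quartiles of the observed log2FC distribution (symmetrized),
        with the M band at half that width."""
        q1, q3 = np.nanpercentile(np.asarray(log2fc_values, float), [25, 75])
        group_hi = float(max(abs(q1), abs(q3)))
        group_hi = min(group_hi, strong)
        return cls(
            strong=strong,
            group_hi=group_hi,
            medium_halfwidth=group_hi / 2,
            hl_slack=hl_slack,
        )


class ASECategory(Enum):
    H_L = "H_L"
    L_H = "L_H"
    HM_or_ML = "H_M_or_M_L"
    LM_or_MH = "L_M_or_M_H"
    M_M = "M_M"
    NONE = "NONE"


class RefinedCategory(Enum):
    """Orientation-resolved reading of an ambiguous category."""

    H_M = "H_M"
    M_L = "M_L"
    L_M = "L_M"
    M_H = "M_H"


#: refinements admissible for each ambiguous category
REFINEMENTS = {
    ASECategory.HM_or_ML: (RefinedCategory.H_M, RefinedCategory.M_L),
    ASECategory.LM_or_MH: (RefinedCategory.L_M, RefinedCategory.M_H),
}

#: (mother state, father state) implied by each refined reading
PARENT_STATES = {
    RefinedCategory.H_M: (ExpressionState.H, ExpressionState.M),
    RefinedCategory.M_L: (ExpressionState.M, ExpressionState.L),
    RefinedCategory.L_M: (ExpressionState.L, ExpressionState.M),
    RefinedCategory.M_H: (ExpressionState.M, ExpressionState.H),
}


@dataclass
class ASECall:
    """A gene's ASE category with per-individual states and evidence."""

    gene_id: str
    category: ASECategory
    states: dict[str, ExpressionState] = field(default_factory=dict)
    mother_log2fc: float = float("nan")
    log2fc: dict[str, float] = field(default_factory=dict)
    resolved: Optional[RefinedCategory] = None
    reason: str = ""
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolved is not None:
            allowed = REFINEMENTS.get(self.category, ())
            if self.resolved not in allowed:
                raise ValueError(
                    f"refinement {self.resolved} invalid for {self.category}"
                )


def state_of(log2fc: float, th: Thresholds = Thresholds()) -> ExpressionState:
    """H/M/L state of one log2FC value; UNASSIGNED in the gap zones."""
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if log2fc >= th.group_hi:
        return ExpressionState.H
    if log2fc <= -th.group_hi:
        return ExpressionState.L
    if abs(log2fc) <= th.medium_halfwidth:
        return ExpressionState.M
    return ExpressionState.UNASSIGNED


def snap_to_band(log2fc: float, th: Thresholds) -> float:
    """Lenient-mode helper: snap a gap-zone value to the nearest band edge."""
    mid = (th.group_hi + th.medium_halfwidth) / 2
    if th.medium_halfwidth < log2fc < th.group_hi:
        return th.medium_halfwidth if log2fc < mid else th.group_hi
    if -th.group_hi < log2fc < -th.medium_halfwidth:
        return -th.medium_halfwidth if log2fc > -mid else -th.group_hi
    return log2fc


def _split_mother_offspring(
    log2fc: Mapping[str, float], family: FamilyDesign
) -> tuple[float, list[float]]:
    missing = [
        i
        for i in (family.mother_id, *family.offspring_ids)
        if i not in log2fc
    ]
    if missing:
        raise ConfigurationError(f"log2fc missing individuals: {missing}")
    mother = float(log2fc[family.mother_id])
    offspring = [float(log2fc[o]) for o in family.offspring_ids]
    return mother, offspring


def classify_gene(
    log2fc: Mapping[str, float],
    family: FamilyDesign,
    th: Thresholds = Thresholds(),
    gate_passed: bool = True,
    mode: str = "strict",
) -> ASECategory:
    """Assign an ASE category from the family log2FC vector.

    Rules are tested in the fixed order H_L, L_H, HM_or_ML, LM_or_MH,
    M_M; the first match wins, so boundary vectors are deterministic.
    Returns NONE when the significance gate failed or no rule matches.
    """
    if not gate_passed:
        return ASECategory.NONE
    mother, offspring = _split_mother_offspring(log2fc, family)
    if mode == "lenient":
        grp = [snap_to_band(o, th) for o in offspring]
        m_band = snap_to_band(mother, th)
    elif mode == "strict":
        grp = offspring
        m_band = mother
    else:
        raise ConfigurationError(f"unknown classification mode {mode!r}")
    mh = th.medium_halfwidth

    # H_L: mother high, father low, all offspring intermediate
    if mother > th.strong and all(
        -th.hl_slack <= o <= mother + th.hl_slack for o in offspring
    ):
        return ASECategory.H_L
    # L_H: mirror of H_L
    if mother < -th.strong and all(
        mother - th.hl_slack <= o <= th.hl_slack for o in offspring
    ):
        return ASECategory.L_H
    # H_M or M_L: offspring split between the mother-like and father-like bands
    if m_band >= th.group_hi:
        g1 = [o for o, s in zip(offspring, grp) if s >= th.group_hi]
        g2 = [o for o, s in zip(offspring, grp) if abs(s) <= mh]
        if (
            len(g1) + len(g2) == len(offspring)
            and g1
            and g2
            and any(o > th.strong for o in grp)
        ):
            return ASECategory.HM_or_ML
    # L_M or M_H: mirror split
    if m_band <= -th.group_hi:
        g1 = [o for o, s in zip(offspring, grp) if s <= -th.group_hi]
        g2 = [o for o, s in zip(offspring, grp) if abs(s) <= mh]
        if (
            len(g1) + len(g2) == len(offspring)
            and g1
            and g2
            and any(o <= -th.strong for o in grp)
        ):
            return ASECategory.LM_or_MH
    # M_M: parents alike, offspring segregate
    if abs(m_band) <= mh:
        states = [state_of(o, th) for o in grp]
        if (
            all(s is not ExpressionState.UNASSIGNED for s in states)
            and len(set(states)) >= 2
            and any(abs(o) >= th.strong for o in offspring)
        ):
            return ASECategory.M_M
    return ASECategory.NONE


def states_for_call(
    category: ASECategory,
    log2fc: Mapping[str, float],
    family: FamilyDesign,
    th: Thresholds = Thresholds(),
    resolved: Optional[RefinedCategory] = None,
    mode: str = "strict",
) -> dict[str, ExpressionState]:
    """Per-individual H/M/L states implied by a category.

    Parent states come from the category letters (for the ambiguous
    categories, from ``resolved`` when available, else from the first
    reading).  H_L and L_H force all offspring to M; the group categories
    assign offspring the state of the parent whose band they fall in.
    Raises if an offspring is UNASSIGNED where the category forbids it.
    """
    if category is ASECategory.NONE:
        raise ValueError("cannot derive states for category NONE")
    mother, offspring = _split_mother_offspring(log2fc, family)
    if mode == "lenient":
        offspring = [snap_to_band(o, th) for o in offspring]
    states: dict[str, ExpressionState] = {}
    mo, fa = family.mother_id, family.father_id
    if category in (ASECategory.H_L, ASECategory.L_H):
        hi = category is ASECategory.H_L
        states[mo] = ExpressionState.H if hi else ExpressionState.L
        states[fa] = ExpressionState.L if hi else ExpressionState.H
        for o in family.offspring_ids:
            states[o] = ExpressionState.M
        return states
    if category in REFINEMENTS:
        reading = resolved if resolved is not None else REFINEMENTS[category][0]
        m_state, f_state = PARENT_STATES[reading]
        states[mo], states[fa] = m_state, f_state
        sign = 1.0 if category is ASECategory.HM_or_ML else -1.0
        for oid, val in zip(family.offspring_ids, offspring):
            if sign * val >= th.group_hi:
                states[oid] = m_state  # tracks the mother's band
            elif abs(val) <= th.medium_halfwidth:
                states[oid] = f_state  # tracks the father (baseline)
            else:
                raise ValueError(
                    f"offspring {oid} log2fc {val:.3f} unassigned under {category}"
                )
        return states
    # M_M
    states[mo] = ExpressionState.M
    states[fa] = ExpressionState.M
    for oid, val in zip(family.offspring_ids, offspring):
        s = state_of(val, th)
        if s is ExpressionState.UNASSIGNED:
            raise ValueError(
                f"offspring {oid} log2fc {val:.3f} unassigned under M_M"
            )
        states[oid] = s
    return states


def call_gene(
    gene_id: str,
    log2fc: Mapping[str, float],
    family: FamilyDesign,
    th: Thresholds = Thresholds(),
    gate_passed: bool = True,
    mode: str = "strict",
) -> ASECall:
    """Classify one gene and package the result as an ASECall.

    A category whose state derivation fails (an UNASSIGNED offspring in a
    category that forbids it) is demoted to NONE with the reason recorded.
    """
    category = classify_gene(log2fc, family, th, gate_passed, mode)
    mother = float(log2fc[family.mother_id])
    call = ASECall(
        gene_id=gene_id,
        category=category,
        mother_log2fc=mother,
        log2fc=dict(log2fc),
    )
    if category is ASECategory.NONE:
        call.reason = "gate_failed" if not gate_passed else "no_rule_matched"
        return call
    try:
        call.states = states_for_call(category, log2fc, family, th, mode=mode)
    except ValueError as exc:
        call.category = ASECategory.NONE
        call.reason = f"demoted: {exc}"
    return call
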