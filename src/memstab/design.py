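"""Combinatorial design over a ladder of nested sequence spaces.

Surviving mutations (phylogeny-allowed and stabilizing, E <= 0) are binned
by K evenly spaced energy thresholds running from the most stabilizing
single mutation up to zero. Each threshold induces a sequence space — the
per-position sets of allowed substitutions — and the lowest-scoring
combination of mutations in each space is selected, yielding designs that
span conservative (few mutations) to promiscuous (many). With the additive
score used here the optimum is the per-position best allowed mutation; a
seeded Monte-Carlo refinement hook is kept for non-additive extensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masking import ConfidenceMask, build_mask
from .membrane import EnergyParams, MembraneFrame, burial, fit_membrane_frame, mutation_energy
from .pssm import MutationCandidate, build_pssm, enumerate_candidates
from .structio import Alignment, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceSpace",
    "Design",
    "PipelineConfig",
    "DesignReport",
    "score_candidates",
    "build_ladder",
    "select_design",
    "run_design_pipeline",
]

DEFAULT_LADDER_SIZE = 18


@dataclass
class SequenceSpace:
    """An energy threshold and the per-position allowed mutations it induces."""

    threshold: float
    allowed: dict[int, list[MutationCandidate]]
    index: int

    @property
    def n_positions(self) -> int:
        return len(self.allowed)

    @property
    def n_mutations(self) -> int:
        return sum(len(v) for v in self.allowed.values())


@dataclass
class Design:
    """A combination of mutations (at most one per position) and its score."""

    mutations: list[MutationCandidate]
    total_score: float
    sequence: str
    space_index: int

    @property
    def name(self) -> str:
        return f"d{self.space_index}"

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def score_candidates(
    model: StructureModel,
    candidates: list[MutationCandidate],
    frame: MembraneFrame,
    params: EnergyParams | None = None,
) -> list[MutationCandidate]:
    """Attach energy scores and drop non-stabilizing (E > 0) mutations."""
    if params is None:
        params = EnergyParams()
    burial_cache: dict[int, float] = {}
    kept: list[MutationCandidate] = []
    for cand in candidates:
        if cand.position not in burial_cache:
            burial_cache[cand.position] = burial(
                model, cand.position, params.burial_radius, params.n_max
            )
        bd = mutation_energy(
            model, cand, frame, params, _burial_value=burial_cache[cand.position]
        )
        cand.energy_score = bd.total
        if cand.energy_score <= 0.0:
            kept.append(cand)
    return kept


def build_ladder(
    candidates: list[MutationCandidate], K: int = DEFAULT_LADDER_SIZE
) -> list[SequenceSpace]:
    """K evenly spaced thresholds from min(E) (strictest) to 0 (loosest).

    Spaces are nested by construction: a stricter threshold admits a subset
    of the mutations of any looser one.
    """
    if K < 1:
        raise ValueError("ladder size K must be >= 1")
    if not candidates:
        logger.warning("no surviving candidates: ladder of %d empty spaces", K)
        thresholds = np.zeros(K)
    else:
        energies = [c.energy_score for c in candidates]
        if any(e is None for e in energies):
            raise ValueError("candidates must be scored before building the ladder")
        lo = min(energies)
        thresholds = np.linspace(lo, 0.0, K) if K > 1 else np.array([0.0])
    spaces = []
    for k, thr in enumerate(thresholds, start=1):
        allowed: dict[int, list[MutationCandidate]] = {}
        for c in candidates:
            if c.energy_score <= thr + 1e-12:
                allowed.setdefault(c.position, []).append(c)
        for pos in allowed:
            allowed[pos].sort(key=lambda c: c.mut_aa)
        spaces.append(SequenceSpace(float(thr), allowed, k))
    return spaces


def select_design(
    space: SequenceSpace,
    wt_sequence: str,
    mode: str = "greedy+refine",
    seed: int = 1,
    n_refine_steps: int = 200,
) -> Design:
    """Lowest-scoring combination of mutations in one sequence space.

    Under the additive model the optimum takes, at every allowed position,
    the lowest-energy mutation (ties broken alphabetically, which the
    per-position sort already guarantees). ``mode='greedy+refine'`` follows
    with a seeded Monte-Carlo pass that can only keep or improve the score;
    with purely additive energies it is a deterministic no-op on the result.
    """
    if mode not in ("greedy", "greedy+refine"):
        raise ValueError(f"unknown selection mode {mode!r}")
    chosen: dict[int, MutationCandidate] = {}
    for pos in sorted(space.allowed):
        best = min(space.allowed[pos], key=lambda c: (c.energy_score, c.mut_aa))
        chosen[pos] = best
    if mode == "greedy+refine" and chosen:
        rng = np.random.default_rng(seed)
        positions = sorted(space.allowed)
        for _ in range(n_refine_steps):
            pos = positions[rng.integers(len(positions))]
            options = space.allowed[pos]
            trial = options[rng.integers(len(options))]
            if trial.energy_score < chosen[pos].energy_score or (
                trial.energy_score == chosen[pos].energy_score
                and trial.mut_aa < chosen[pos].mut_aa
            ):
                chosen[pos] = trial
    mutations = [chosen[p] for p in sorted(chosen)]
    seq = list(wt_sequence)
    for m in mutations:
        if seq[m.position - 1] != m.wt_aa:
            raise ValueError(
                f"candidate wild-type {m.wt_aa} at {m.position} disagrees with sequence"
            )
        seq[m.position - 1] = m.mut_aa
    total = float(sum(m.energy_score for m in mutations))
    return Design(mutations, total, "".join(seq), space.index)


@dataclass
class PipelineConfig:
    """Every knob of the one-step design workflow, logged with each run."""

    plddt_threshold: float = 90.0
    flank: int = 2
    pssm_alpha: float = 1.0
    pssm_weighting: str = "henikoff"
    ladder_size: int = DEFAULT_LADDER_SIZE
    selection_mode: str = "greedy+refine"
    seed: int = 1
    half_thickness: float = 15.0
    tm_ranges: list[tuple[int, int]] = field(default_factory=list)
    excluded_positions: list[int] = field(default_factory=list)
    energy: EnergyParams = field(default_factory=EnergyParams)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "plddt_threshold", "flank", "pssm_alpha", "pssm_weighting",
                "ladder_size", "selection_mode", "seed", "half_thickness",
                "tm_ranges", "excluded_positions",
            )
        }
        d["energy"] = self.energy.as_dict()
        return d


@dataclass
class DesignReport:
    """Full record of one pipeline run."""

    designs: list[Design]
    mask: ConfidenceMask
    candidates: list[MutationCandidate]
    spaces: list[SequenceSpace]
    config: PipelineConfig
    log: list[str]

    def mutation_table(self) -> pd.DataFrame:
        rows = []
        for d in self.designs:
            for m in d.mutations:
                rows.append(
                    {
                        "space_index": d.space_index,
                        "position": m.position,
                        "wt": m.wt_aa,
                        "mut": m.mut_aa,
                        "pssm_score": m.pssm_score,
                        "energy_score": m.energy_score,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["space_index", "position", "wt", "mut", "pssm_score", "energy_score"],
        )

    def designs_fasta(self, width: int = 60) -> str:
        out = []
        for d in self.designs:
            out.append(f">{d.name} n_mutations={d.n_mutations} score={d.total_score:.4f}")
            for i in range(0, len(d.sequence), width):
                out.append(d.sequence[i : i + width])
        return "\n".join(out) + "\n"


def run_design_pipeline(
    model: StructureModel,
    alignment: Alignment,
    config: PipelineConfig | None = None,
) -> DesignReport:
    """mask -> PSSM -> phylogenetic filter -> energy -> ladder -> selection.

    Runs the whole one-step workflow and returns all K designs with a full
    parameter log. Any stage failure aborts with a stage-tagged message.
    """
    if config is None:
        config = PipelineConfig()
    log: list[str] = [f"config: {config.as_dict()}"]

    def stage(name):
        log.append(f"stage: {name}")

    try:
        stage("mask")
        mask = build_mask(model.plddt, config.plddt_threshold, config.flank)
        if config.excluded_positions:
            mask = ConfidenceMask(
                mask.length,
                frozenset(mask.restricted) | set(config.excluded_positions),
                mask.threshold,
                mask.flank,
            )
        log.append(f"restricted {len(mask.restricted)}/{mask.length} positions")

        stage("pssm")
        if alignment.query_sequence != model.sequence:
            raise ValueError("alignment query sequence differs from model sequence")
        profile = build_pssm(alignment, config.pssm_alpha, weighting=config.pssm_weighting)

        stage("candidates")
        candidates = enumerate_candidates(profile, model.sequence, mask)
        log.append(f"{len(candidates)} phylogeny-allowed candidates")

        stage("energy")
        if config.tm_ranges:
            frame = fit_membrane_frame(model, config.tm_ranges, config.half_thickness)
        else:
            # no membrane topology given: slab far away, all positions aqueous
            frame = MembraneFrame(
                np.array([0.0, 0.0, -1e6]), np.array([0.0, 0.0, 1.0]),
                config.half_thickness,
            )
        scored = score_candidates(model, candidates, frame, config.energy)
        log.append(f"{len(scored)} stabilizing candidates (E <= 0)")

        stage("ladder")
        spaces = build_ladder(scored, config.ladder_size)

        stage("selection")
        designs = [
            select_design(sp, model.sequence, config.selection_mode, config.seed)
            for sp in spaces
        ]
        log.append(
            "mutation counts: " + ",".join(str(d.n_mutations) for d in designs)
        )
    except Exception as exc:
        raise RuntimeError(f"design pipeline failed at {log[-1]}: {exc}") from exc
    return DesignReport(designs, mask, scored, spaces, config, log)
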