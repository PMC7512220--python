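"""Synthetic SWATH-like cohort generator with known ground truth.

Emulates a case/control DIA quantification experiment at the fragment-ion
level: each protein contributes several tryptic peptides, each peptide several
fragment ions, and each of the ``(n_cases + n_controls) * n_replicates`` runs
records one peak intensity per observed fragment.  A configurable subset of
case samples (the "signal subgroup") carries planted abundance effects on a
configurable set of proteins; the remaining cases are generated from the
control distribution, reproducing the geometry of a cohort in which a minority
of cases is indistinguishable from controls.

Intensities are drawn on a log10 scale and exponentiated, so baseline fragment
abundances are long-tailed and the "top peptides / top fragments" rollup
selection downstream is non-trivial.  Missing fragment observations are absent
rows, not zeros.  All randomness flows from a single seed, split into one
independent stream per generation stage, so identical configurations yield
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["CohortConfig", "Cohort", "generate_cohort", "planted_annotation"]

_LN10 = np.log(10.0)


def _cv_to_log10_sd(cv: float) -> float:
    """Standard deviation on log10 scale of a log-normal with the given CV."""
    return float(np.sqrt(np.log1p(cv * cv)) / _LN10)


@dataclass(frozen=True)
class CohortConfig:
    """Design and noise parameters of a synthetic cohort.

    Defaults reproduce the study design of an 11-case / 9-control PBMC cohort
    measured in technical triplicate, with a 9-of-11 case subgroup carrying
    the disease signal, ~3000 quantified proteins and 99 planted differential
    proteins with |log10 fold-change| between 0.2 and 0.5 (47% increases).
    """

    n_cases: int = 11
    n_controls: int = 9
    n_subgroup_cases: int = 9
    n_proteins: int = 2970
    peptides_per_protein: tuple[int, int] = (4, 18)
    fragments_per_peptide: tuple[int, int] = (6, 9)
    n_replicates: int = 3
    n_de_proteins: int = 99
    effect_log10fc: tuple[float, float] = (0.2, 0.5)
    frac_up: float = 47 / 99
    noise_cv: float = 0.20
    replicate_cv: float = 0.10
    run_depth_factor_sd: float = 0.15
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        def bad(name, why):
            raise ConfigurationError(f"invalid CohortConfig field '{name}': {why}")

        for name in ("n_cases", "n_controls", "n_proteins", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                bad(name, f"must be an integer >= 1, got {v!r}")
        if not isinstance(self.n_de_proteins, (int, np.integer)) or self.n_de_proteins < 0:
            bad("n_de_proteins", f"must be an integer >= 0, got {self.n_de_proteins!r}")
        if self.n_de_proteins > self.n_proteins:
            bad("n_de_proteins", "exceeds n_proteins")
        if not (0 <= self.n_subgroup_cases <= self.n_cases):
            bad("n_subgroup_cases", "must satisfy 0 <= n_subgroup_cases <= n_cases")
        if not (0.0 <= self.frac_up <= 1.0):
            bad("frac_up", f"must lie in [0, 1], got {self.frac_up!r}")
        for name in ("peptides_per_protein", "fragments_per_peptide"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                bad(name, f"range must satisfy 1 <= low <= high, got ({lo}, {hi})")
        lo, hi = self.effect_log10fc
        if not (0.0 <= lo <= hi):
            bad("effect_log10fc", f"range must satisfy 0 <= low <= high, got ({lo}, {hi})")
        for name in ("noise_cv", "replicate_cv", "run_depth_factor_sd"):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            bad("missing_rate", f"must lie in [0, 1), got {self.missing_rate!r}")
        if not isinstance(self.seed, (int, np.integer)):
            bad("seed", f"must be an integer, got {self.seed!r}")


class Cohort(NamedTuple):
    """A generated cohort: fragment table, run/sample metadata and truth."""

    fragments: pd.DataFrame  # protein_id, peptide_id, fragment_id, run_id, intensity
    runs: pd.DataFrame       # run_id, sample_id, replicate_index
    samples: pd.DataFrame    # sample_id, group
    truth: pd.DataFrame      # protein_id, is_de, true_log10fc, subgroup_members


# Fixed baseline distribution of the simulated proteome (log10 units).  The
# spread across proteins / peptides / fragments gives the long-tailed linear-
# scale intensities typical of extracted DIA peak areas; the absolute level is
# arbitrary (the pipeline is scale-free after normalization).
_PROTEIN_BASE_MEAN = 5.0
_PROTEIN_BASE_SD = 0.8
_PEPTIDE_SD = 0.5
_FRAGMENT_SD = 0.35


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a fragment-level cohort with planted ground truth.

    Returns a :class:`Cohort` whose ``fragments`` table is long-format with one
    row per observed (fragment, run) peak; fragments unobserved in a run
    (probability ``missing_rate``) are absent rows.  ``truth`` records, per
    protein, whether an effect was planted and its signed log10 magnitude,
    plus the identity of the subgroup cases carrying the signal.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    r_design, r_effect, r_sample, r_rep, r_depth, r_miss = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    # --- identifiers ------------------------------------------------------
    case_ids = [f"P{i + 1}" for i in range(cfg.n_cases)]
    control_ids = [f"C{i + 1}" for i in range(cfg.n_controls)]
    sample_ids = case_ids + control_ids
    subgroup = case_ids[: cfg.n_subgroup_cases]
    n_samples = len(sample_ids)

    run_ids, run_sample_idx, run_rep = [], [], []
    for si, sid in enumerate(sample_ids):
        for k in range(cfg.n_replicates):
            run_ids.append(f"{sid}_r{k + 1}")
            run_sample_idx.append(si)
            run_rep.append(k + 1)
    run_sample_idx = np.asarray(run_sample_idx)
    n_runs = len(run_ids)

    width = len(str(cfg.n_proteins))
    protein_ids = [f"PROT{i + 1:0{width}d}" for i in range(cfg.n_proteins)]

    # --- proteome structure ----------------------------------------------
    lo, hi = cfg.peptides_per_protein
    n_pep = r_design.integers(lo, hi + 1, size=cfg.n_proteins)
    pep_protein = np.repeat(np.arange(cfg.n_proteins), n_pep)
    pep_within = np.concatenate([np.arange(k) for k in n_pep])
    n_peptides = pep_protein.size

    lo, hi = cfg.fragments_per_peptide
    n_frag = r_design.integers(lo, hi + 1, size=n_peptides)
    frag_peptide = np.repeat(np.arange(n_peptides), n_frag)
    frag_within = np.concatenate([np.arange(k) for k in n_frag])
    frag_protein = pep_protein[frag_peptide]
    n_fragments = frag_peptide.size

    base = r_design.normal(_PROTEIN_BASE_MEAN, _PROTEIN_BASE_SD, size=cfg.n_proteins)
    pep_fac = r_design.normal(0.0, _PEPTIDE_SD, size=n_peptides)
    frag_fac = r_design.normal(0.0, _FRAGMENT_SD, size=n_fragments)
    frag_log10 = base[frag_protein] + pep_fac[frag_peptide] + frag_fac

    # --- planted effects --------------------------------------------------
    true_lfc = np.zeros(cfg.n_proteins)
    if cfg.n_de_proteins > 0:
        de_idx = r_effect.choice(cfg.n_proteins, size=cfg.n_de_proteins, replace=False)
        elo, ehi = cfg.effect_log10fc
        mag = r_effect.uniform(elo, ehi, size=cfg.n_de_proteins)
        n_up = int(round(cfg.frac_up * cfg.n_de_proteins))
        sign = np.full(cfg.n_de_proteins, -1.0)
        up_pos = r_effect.choice(cfg.n_de_proteins, size=n_up, replace=False)
        sign[up_pos] = 1.0
        true_lfc[de_idx] = sign * mag

    in_subgroup = np.zeros(n_samples, dtype=bool)
    in_subgroup[: cfg.n_subgroup_cases] = True  # cases precede controls

    # --- noise and assembly ----------------------------------------------
    sd_bio = _cv_to_log10_sd(cfg.noise_cv)
    sd_rep = _cv_to_log10_sd(cfg.replicate_cv)
    # per-(protein, sample) biological variation shared by a sample's replicates
    bio = r_sample.normal(0.0, sd_bio, size=(cfg.n_proteins, n_samples)) if sd_bio else np.zeros((cfg.n_proteins, n_samples))
    depth = r_depth.normal(0.0, cfg.run_depth_factor_sd, size=n_runs)

    log10_i = np.empty((n_fragments, n_runs))
    log10_i[:] = frag_log10[:, None]
    shift = true_lfc[:, None] * in_subgroup[None, :] + bio  # protein x sample
    log10_i += shift[frag_protein][:, run_sample_idx]
    if sd_rep:
        log10_i += r_rep.normal(0.0, sd_rep, size=(n_fragments, n_runs))
    log10_i += depth[None, :]

    intensity = np.power(10.0, log10_i, out=log10_i)  # in place, frees nothing extra

    keep = np.ones(intensity.size, dtype=bool)
    if cfg.missing_rate > 0:
        keep = r_miss.random(intensity.size) >= cfg.missing_rate

    frag_row = np.repeat(np.arange(n_fragments), n_runs)[keep]
    run_col = np.tile(np.arange(n_runs), n_fragments)[keep]
    values = intensity.ravel()[keep]

    pep_names = [f"{protein_ids[p]}_pep{j + 1:02d}" for p, j in zip(pep_protein, pep_within)]
    frag_names = [
        f"{pep_names[q]}_f{j + 1}" for q, j in zip(frag_peptide, frag_within)
    ]

    fragments = pd.DataFrame(
        {
            "protein_id": pd.Categorical.from_codes(frag_protein[frag_row], protein_ids),
            "peptide_id": pd.Categorical.from_codes(frag_peptide[frag_row], pep_names),
            "fragment_id": pd.Categorical.from_codes(frag_row, frag_names),
            "run_id": pd.Categorical.from_codes(run_col, run_ids),
            "intensity": values,
        }
    )

    runs = pd.DataFrame(
        {
            "run_id": run_ids,
            "sample_id": [sample_ids[i] for i in run_sample_idx],
            "replicate_index": run_rep,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
        }
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "is_de": true_lfc != 0.0,
            "true_log10fc": true_lfc,
            "subgroup_members": ";".join(subgroup),
        }
    )
    return Cohort(fragments, runs, samples, truth)


def planted_annotation(truth: pd.DataFrame, flag_name: str = "planted") -> pd.DataFrame:
    """Annotation table flagging the planted differential proteins.

    Convenience for the subset-specificity test on synthetic cohorts: the
    flagged panel is exactly the generator's planted protein set.
    """
    return pd.DataFrame(
        {"protein_id": truth["protein_id"], flag_name: truth["is_de"].astype(int)}
    )
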