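"""Reading, harmonizing and selecting genetic instruments.

Summary-statistics MR needs per-SNP association estimates for one outcome,
K exposures and one independent *selection* cohort per exposure (the
three-sample design: selection never touches the cohorts used for
estimation, which removes winner's-curse bias).  This module merges the
per-trait tables onto a common effect allele, applies the combined
selection-p-value rule, and prunes SNPs to pairwise linkage-equilibrium
with a greedy clumper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: required columns of every per-trait summary-statistics table
TABLE_COLUMNS = ["SNP", "effect_allele", "other_allele", "beta", "se", "pval"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    """A/T and G/C SNPs cannot be strand-resolved without frequencies."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class SNPRecord:
    """Harmonized summary statistics for one SNP across all cohorts.

    ``gamma_hat``/``se_gamma`` are the per-allele exposure associations and
    standard errors (length K), ``Gamma_hat``/``se_Gamma`` the outcome
    association (log odds ratio for binary outcomes), and ``sel_pvalues``
    the K selection-cohort p-values used only for instrument choice.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    gamma_hat: np.ndarray
    se_gamma: np.ndarray
    Gamma_hat: float
    se_Gamma: float
    sel_pvalues: np.ndarray

    def __post_init__(self) -> None:
        self.gamma_hat = np.atleast_1d(np.asarray(self.gamma_hat, dtype=float))
        self.se_gamma = np.atleast_1d(np.asarray(self.se_gamma, dtype=float))
        self.sel_pvalues = np.atleast_1d(np.asarray(self.sel_pvalues, dtype=float))
        if not (len(self.gamma_hat) == len(self.se_gamma) == len(self.sel_pvalues)):
            raise ValueError(f"SNP {self.snp_id}: exposure fields disagree in length")
        if self.se_Gamma <= 0 or np.any(self.se_gamma <= 0):
            raise ValueError(f"SNP {self.snp_id}: standard errors must be positive")
        if np.any((self.sel_pvalues < 0) | (self.sel_pvalues > 1)):
            raise ValueError(f"SNP {self.snp_id}: selection p-values outside [0, 1]")
        if self.effect_allele.upper() == self.other_allele.upper():
            raise ValueError(f"SNP {self.snp_id}: effect and other allele identical")

    @property
    def K(self) -> int:
        return len(self.gamma_hat)


@dataclass
class HarmonizedStudy:
    """Merged three-sample summary statistics, one record per SNP."""

    records: list[SNPRecord]
    trait_names: list[str]
    outcome_is_binary: bool = False

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in harmonized study")
        if self.records:
            K = self.records[0].K
            if any(r.K != K for r in self.records):
                raise ValueError("records disagree in exposure count")
        if len(self.trait_names) != self.K + 1:
            raise ValueError("trait_names must have K+1 entries (outcome first)")

    @property
    def K(self) -> int:
        return self.records[0].K if self.records else len(self.trait_names) - 1

    @property
    def n_snps(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    # dense views used by the numerical modules
    @property
    def gamma(self) -> np.ndarray:  # (p, K)
        return np.array([r.gamma_hat for r in self.records])

    @property
    def se_gamma(self) -> np.ndarray:  # (p, K)
        return np.array([r.se_gamma for r in self.records])

    @property
    def Gamma(self) -> np.ndarray:  # (p,)
        return np.array([r.Gamma_hat for r in self.records])

    @property
    def se_Gamma(self) -> np.ndarray:  # (p,)
        return np.array([r.se_Gamma for r in self.records])

    @property
    def sel_pvalues(self) -> np.ndarray:  # (p, K)
        return np.array([r.sel_pvalues for r in self.records])

    def record(self, snp_id: str) -> SNPRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def subset(self, snp_ids: Sequence[str]) -> "HarmonizedStudy":
        wanted = set(snp_ids)
        return HarmonizedStudy(
            records=[r for r in self.records if r.snp_id in wanted],
            trait_names=list(self.trait_names),
            outcome_is_binary=self.outcome_is_binary,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat table with per-exposure columns suffixed by trait name."""
        rows = []
        for r in self.records:
            row = {
                "SNP": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": r.Gamma_hat,
                "se": r.se_Gamma,
            }
            for k, name in enumerate(self.trait_names[1:]):
                row[f"beta_{name}"] = r.gamma_hat[k]
                row[f"se_{name}"] = r.se_gamma[k]
                row[f"sel_pval_{name}"] = r.sel_pvalues[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tables(self) -> tuple[pd.DataFrame, list[pd.DataFrame], list[pd.DataFrame]]:
        """Re-emit (outcome, exposure, selection) tables in the input schema.

        Round-tripping through :func:`harmonize` is the identity, which is
        the contract tests rely on.
        """
        base = {
            "SNP": self.snp_ids,
            "effect_allele": [r.effect_allele for r in self.records],
            "other_allele": [r.other_allele for r in self.records],
        }
        outcome = pd.DataFrame({**base, "beta": self.Gamma, "se": self.se_Gamma,
                                "pval": np.ones(self.n_snps)})
        exposures, selections = [], []
        for k in range(self.K):
            exposures.append(pd.DataFrame({**base, "beta": self.gamma[:, k],
                                           "se": self.se_gamma[:, k],
                                           "pval": np.ones(self.n_snps)}))
            selections.append(pd.DataFrame({**base, "beta": self.gamma[:, k],
                                            "se": self.se_gamma[:, k],
                                            "pval": self.sel_pvalues[:, k]}))
        return outcome, exposures, selections


@dataclass
class InstrumentSet:
    """Instruments chosen at one selection threshold (optionally clumped)."""

    parent: HarmonizedStudy
    selected_ids: list[str]
    threshold: float
    r2_threshold: float | None = None

    def __post_init__(self) -> None:
        parent_ids = set(self.parent.snp_ids)
        missing = [s for s in self.selected_ids if s not in parent_ids]
        if missing:
            raise ValueError(f"selected ids not in parent study: {missing[:5]}")

    @property
    def n_instruments(self) -> int:
        return len(self.selected_ids)

    def study(self) -> HarmonizedStudy:
        return self.parent.subset(self.selected_ids)


def read_table(path) -> pd.DataFrame:
    """Read a per-trait summary-statistics table (TSV or CSV, sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_ld_matrix(path) -> pd.DataFrame:
    """Square r² matrix as TSV with SNP ids as header row and index column."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.columns = mat.columns.astype(str)
    mat.index = mat.index.astype(str)
    return mat


def _check_table(df: pd.DataFrame, label: str) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{label}: missing required columns {missing}")
    dup = df["SNP"][df["SNP"].duplicated()]
    if len(dup):
        raise ValueError(f"{label}: duplicated snp_id {dup.iloc[0]!r}")
    return df.set_index("SNP")


def harmonize(
    outcome_table: pd.DataFrame,
    exposure_tables: Sequence[pd.DataFrame],
    selection_tables: Sequence[pd.DataFrame],
    trait_names: Sequence[str] | None = None,
    outcome_is_binary: bool = False,
) -> HarmonizedStudy:
    """Merge per-trait tables onto a common effect allele.

    The outcome table defines the reference allele orientation.  For each
    other table a SNP listed with swapped effect/other alleles has its
    association sign flipped; strand-ambiguous palindromic SNPs (A/T, G/C)
    are dropped, as are SNPs with allele combinations irreconcilable with
    the outcome's or with any missing field.  Drop counts are logged.
    """
    if len(exposure_tables) != len(selection_tables):
        raise ValueError("need one selection table per exposure table")
    K = len(exposure_tables)
    if trait_names is None:
        trait_names = ["outcome"] + [f"exposure{k + 1}" for k in range(K)]
    trait_names = list(trait_names)

    out = _check_table(outcome_table, "outcome")
    exps = [_check_table(t, f"exposure {k}") for k, t in enumerate(exposure_tables)]
    sels = [_check_table(t, f"selection {k}") for k, t in enumerate(selection_tables)]

    common = out.index
    for t in exps + sels:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise ValueError("no SNP present in all tables; harmonization impossible")

    n_ambiguous = n_mismatch = n_missing = 0
    records: list[SNPRecord] = []
    for snp in common:
        o = out.loc[snp]
        ea, oa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        if _is_palindromic(ea, oa):
            n_ambiguous += 1
            continue

        def aligned_beta(row) -> float | None:
            a1, a2 = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
            if _is_palindromic(a1, a2):
                return None
            if (a1, a2) == (ea, oa):
                return float(row["beta"])
            if (a1, a2) == (oa, ea):
                return -float(row["beta"])
            # strand flip relative to the outcome orientation
            c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
            if (c1, c2) == (ea, oa):
                return float(row["beta"])
            if (c1, c2) == (oa, ea):
                return -float(row["beta"])
            return None

        fields = [float(o["beta"]), float(o["se"])]
        gamma, se_g, sel_p = [], [], []
        ok = True
        for k in range(K):
            e, s = exps[k].loc[snp], sels[k].loc[snp]
            b = aligned_beta(e)
            if b is None:
                ok = False
                n_mismatch += 1
                break
            gamma.append(b)
            se_g.append(float(e["se"]))
            sel_p.append(float(s["pval"]))
        if not ok:
            continue
        if any(not np.isfinite(v) for v in fields + gamma + se_g + sel_p):
            n_missing += 1
            continue
        records.append(SNPRecord(
            snp_id=str(snp), effect_allele=ea, other_allele=oa,
            gamma_hat=np.array(gamma), se_gamma=np.array(se_g),
            Gamma_hat=fields[0], se_Gamma=fields[1],
            sel_pvalues=np.array(sel_p),
        ))

    logger.info(
        "harmonize: %d SNPs kept (%d ambiguous, %d allele-mismatched, "
        "%d with missing fields dropped)",
        len(records), n_ambiguous, n_mismatch, n_missing,
    )
    if not records:
        raise ValueError("harmonization left no usable SNP")
    return HarmonizedStudy(records=records, trait_names=trait_names,
                           outcome_is_binary=outcome_is_binary)


def combined_selection_p(sel_pvalues: np.ndarray) -> np.ndarray:
    """Bonferroni-combined selection p-value K·min_k(p_jk), capped at 1."""
    sel = np.atleast_2d(sel_pvalues)
    return np.minimum(1.0, sel.shape[1] * sel.min(axis=1))


def select_instruments(study: HarmonizedStudy, threshold: float) -> list[str]:
    """Candidate instruments whose combined selection p passes ``threshold``."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly between 0 and 1")
    combined = combined_selection_p(study.sel_pvalues)
    return [sid for sid, p in zip(study.snp_ids, combined) if p <= threshold]


def ld_clump(
    candidates: Sequence[str],
    sort_pvalues: Mapping[str, float],
    ld_r2: pd.DataFrame | Mapping[tuple[str, str], float],
    r2_threshold: float = 0.001,
) -> list[str]:
    """Greedy LD clumping: keep the most significant SNP, discard its LD
    partners above ``r2_threshold``, repeat.  Output is in keep order."""

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        if isinstance(ld_r2, pd.DataFrame):
            if a not in ld_r2.index or b not in ld_r2.columns:
                raise KeyError(f"no r² entry for pair ({a}, {b})")
            return float(ld_r2.loc[a, b])
        key = (a, b) if (a, b) in ld_r2 else (b, a)
        if key not in ld_r2:
            raise KeyError(f"no r² entry for pair ({a}, {b})")
        return float(ld_r2[key])

    remaining = sorted(candidates, key=lambda s: (sort_pvalues[s], s))
    kept: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [s for s in remaining if r2(best, s) <= r2_threshold]
    return kept


def build_instrument_set(
    study: HarmonizedStudy,
    threshold: float,
    ld_r2: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
    assume_independent: bool = False,
) -> InstrumentSet:
    """Select candidates at ``threshold`` and clump them to independence.

    LD information is required unless ``assume_independent`` is set (for
    data that is independent by construction, e.g. simulations).
    """
    candidates = select_instruments(study, threshold)
    if ld_r2 is None:
        if not assume_independent:
            raise ValueError(
                "no LD matrix supplied; pass assume_independent=True only if "
                "the candidate SNPs are known to be independent"
            )
        selected = candidates
        r2_used = None
    else:
        combined = dict(zip(study.snp_ids, combined_selection_p(study.sel_pvalues)))
        selected = ld_clump(candidates, combined, ld_r2, r2_threshold)
        r2_used = r2_threshold
        logger.info("ld_clump: %d of %d candidates kept at r2 <= %g",
                    len(selected), len(candidates), r2_threshold)
    return InstrumentSet(parent=study, selected_ids=selected,
                         threshold=threshold, r2_threshold=r2_used)
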