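"""Point-mutation classification and codon-level covariates.

Works on a single bacterial coding sequence (translation table 11).
Provides the codon adaptation index (CAI, Sharp & Li geometric mean of
relative-adaptiveness weights from a highly expressed reference gene set),
the tRNA adaptation index (tAI, dos Reis weights from decoding-tRNA gene
copy numbers with standard wobble penalties), per-mutation deltas of both,
mRNA folding windows centred on each mutation, and a translational-ramp
test (rare-codon enrichment near the start codon).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "BACTERIAL_TABLE",
    "CodingSequence",
    "PointMutation",
    "MutationClass",
    "CodonUsageTable",
    "TRNACopyTable",
    "classify_mutation",
    "compute_cai",
    "compute_tai",
    "delta_metrics",
    "extract_mrna_window",
    "ramp_test",
    "MrnaWindow",
    "RampTestResult",
]

BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOPS = frozenset(BACTERIAL_TABLE.stop_codons)
_STARTS = frozenset({"ATG", "GTG", "TTG"})
_BASES = "ACGT"
_SENSE_CODONS = tuple(sorted(BACTERIAL_TABLE.forward_table))

#: synonymous families: amino acid -> codons (sense codons only)
_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _aa in BACTERIAL_TABLE.forward_table.items():
    _FAMILIES.setdefault(_aa, ())
    _FAMILIES[_aa] += (_c,)

#: codons excluded from CAI: single-codon families have weight 1 by
#: construction and carry no usage information (standard Sharp & Li rule)
_CAI_EXCLUDED = frozenset(
    c for aa, codons in _FAMILIES.items() if len(codons) == 1 for c in codons)


class ReferenceMismatchError(ValueError):
    """The stated reference base does not match the CDS (coordinate or strand mistake)."""


def _translate(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in _STOPS:
        return "*"
    return BACTERIAL_TABLE.forward_table[codon]


@dataclass(frozen=True)
class CodingSequence:
    """A bacterial CDS with optional flanking sequence.

    Coordinates are 1-based on the CDS; position 1 is the first base of the
    start codon.  Flanks are used only for mRNA-window extraction.
    """

    id: str
    seq: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        object.__setattr__(self, "flank5", self.flank5.upper())
        object.__setattr__(self, "flank3", self.flank3.upper())
        if set(seq) - set(_BASES):
            raise ValueError(f"{self.id}: non-ACGT characters in CDS")
        if len(seq) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length {len(seq)} not a multiple of 3")
        codons = self.codons
        if codons[0] not in _STARTS:
            raise ValueError(f"{self.id}: {codons[0]} is not a bacterial start codon")
        if codons[-1] not in _STOPS:
            raise ValueError(f"{self.id}: CDS does not end with a stop codon")
        if any(c in _STOPS for c in codons[:-1]):
            raise ValueError(f"{self.id}: internal stop codon in frame")

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.seq[i:i + 3] for i in range(0, len(self.seq), 3))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """All codons except the terminal stop."""
        return self.codons[:-1]

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon_at(self, codon_index: int) -> str:
        """Codon by 1-based index."""
        return self.seq[(codon_index - 1) * 3: codon_index * 3]

    def protein(self) -> str:
        return str(Seq(self.seq[:-3]).translate(table=11))

    def with_substitution(self, cds_position: int, alt_base: str) -> "CodingSequence":
        """Mutant CDS string (no validation of the mutant reading frame)."""
        s = self.seq
        mutant = s[:cds_position - 1] + alt_base + s[cds_position:]
        obj = object.__new__(CodingSequence)
        object.__setattr__(obj, "id", f"{self.id}|{cds_position}{alt_base}")
        object.__setattr__(obj, "seq", mutant)
        object.__setattr__(obj, "flank5", self.flank5)
        object.__setattr__(obj, "flank3", self.flank3)
        return obj


@dataclass(frozen=True)
class PointMutation:
    """A single-nucleotide substitution in CDS coordinates (1-based)."""

    cds_position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_base", self.ref_base.upper())
        object.__setattr__(self, "alt_base", self.alt_base.upper())
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError("bases must be one of A, C, G, T")
        if self.ref_base == self.alt_base:
            raise ValueError("alt_base must differ from ref_base")
        if self.cds_position < 1:
            raise ValueError("cds_position is 1-based and must be >= 1")

    @property
    def codon_index(self) -> int:
        """1-based index of the codon containing the substitution."""
        return (self.cds_position - 1) // 3 + 1

    @property
    def codon_position(self) -> int:
        """Position of the substituted base within its codon (1-3)."""
        return (self.cds_position - 1) % 3 + 1

    @property
    def site_label(self) -> str:
        """Codon-position-alt notation, e.g. ``39-3T``."""
        return f"{self.codon_index}-{self.codon_position}{self.alt_base}"

    def protein_label(self, cds: "CodingSequence") -> str:
        """Protein-level notation, e.g. ``G38G`` or ``W12*``."""
        ref_codon = cds.codon_at(self.codon_index)
        alt_codon = _mutant_codon(ref_codon, self.codon_position, self.alt_base)
        return f"{_translate(ref_codon)}{self.codon_index}{_translate(alt_codon)}"


class MutationClass:
    """Functional classes of a point substitution in a sense codon."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONSENSE = "nonsense"
    ALL = (SYNONYMOUS, NONSYNONYMOUS, NONSENSE)


def _mutant_codon(codon: str, codon_position: int, alt: str) -> str:
    i = codon_position - 1
    return codon[:i] + alt + codon[i + 1:]


def classify_mutation(cds: CodingSequence, mut: PointMutation) -> str:
    """Classify a substitution as synonymous / nonsynonymous / nonsense.

    Raises :class:`ReferenceMismatchError` when the stated reference base
    disagrees with the CDS, and :class:`ValueError` for positions outside
    the CDS or inside the terminal stop codon.
    """
    if not 1 <= mut.cds_position <= len(cds.seq):
        raise ValueError(
            f"position {mut.cds_position} outside CDS of length {len(cds.seq)}")
    if cds.seq[mut.cds_position - 1] != mut.ref_base:
        raise ReferenceMismatchError(
            f"reference base at {mut.cds_position} is "
            f"{cds.seq[mut.cds_position - 1]}, not {mut.ref_base}")
    if mut.codon_index == cds.n_codons:
        raise ValueError("substitution in the terminal stop codon is not classifiable")
    ref_codon = cds.codon_at(mut.codon_index)
    alt_codon = _mutant_codon(ref_codon, mut.codon_position, mut.alt_base)
    if alt_codon in _STOPS:
        return MutationClass.NONSENSE
    if _translate(alt_codon) == _translate(ref_codon):
        return MutationClass.SYNONYMOUS
    return MutationClass.NONSYNONYMOUS


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonUsageTable:
    """Relative-adaptiveness weights ``w_c`` from a reference gene set.

    ``w_c = count_c / max(count over the synonymous family)``; zero counts
    are smoothed to 0.5 before normalisation so no sense codon gets weight 0.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(_SENSE_CODONS) - set(self.weights)
        if missing:
            raise ValueError(f"missing weights for codons: {sorted(missing)}")
        for c, w in self.weights.items():
            if not 0 < w <= 1:
                raise ValueError(f"weight for {c} must lie in (0, 1], got {w}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "CodonUsageTable":
        counts = {c: (counts.get(c, 0) or 0.5) for c in _SENSE_CODONS}
        weights: dict[str, float] = {}
        for codons in _FAMILIES.values():
            top = max(counts[c] for c in codons)
            for c in codons:
                weights[c] = counts[c] / top
        return cls(weights)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "CodonUsageTable":
        """Count codons over reference CDSs (terminal stops ignored)."""
        counts: Counter[str] = Counter()
        for s in seqs:
            s = str(s).upper()
            counts.update(s[i:i + 3] for i in range(0, len(s) - len(s) % 3, 3))
        counts = Counter({c: n for c, n in counts.items() if c in BACTERIAL_TABLE.forward_table})
        if not counts:
            raise ValueError("reference set contains no sense codons")
        return cls.from_counts(counts)

    def weight(self, codon: str) -> float:
        return self.weights[codon]


def _cai_codons(codons: Sequence[str]) -> list[str]:
    return [c for c in codons if c in BACTERIAL_TABLE.forward_table
            and c not in _CAI_EXCLUDED]


def compute_cai(seq_or_codons, usage: CodonUsageTable):
    """Codon adaptation index: geometric mean of relative-adaptiveness weights.

    Codons in single-codon families (Met, Trp) and stop codons are excluded,
    per the standard definition.  Returns ``(cai, per_codon_weights)`` where
    the weights cover the included codons in sequence order.
    """
    if isinstance(seq_or_codons, CodingSequence):
        codons: Sequence[str] = seq_or_codons.sense_codons
    elif isinstance(seq_or_codons, str):
        s = seq_or_codons.upper()
        codons = [s[i:i + 3] for i in range(0, len(s) - len(s) % 3, 3)]
    else:
        codons = [c.upper() for c in seq_or_codons]
    included = _cai_codons(codons)
    if not included:
        raise ValueError("no codons eligible for CAI (all single-family or stop)")
    w = np.array([usage.weight(c) for c in included])
    return float(np.exp(np.mean(np.log(w)))), w


# ---------------------------------------------------------------------------
# tAI
# ---------------------------------------------------------------------------

#: default wobble selective constraints s (dos Reis et al. values);
#: Watson-Crick pairings have s = 0
DEFAULT_WOBBLE_S = {
    "G:U": 0.41,    # anticodon G34 reading codon-3 U
    "I:C": 0.28,    # inosine (from A34) reading C
    "I:A": 0.9999,  # inosine reading A
    "U:G": 0.68,    # anticodon U34 reading G
    "L:A": 0.89,    # lysidine-modified C34 reading AUA (bacterial Ile)
}

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TRNACopyTable:
    """tRNA gene copy numbers keyed by anticodon (DNA alphabet, 5'->3')."""

    copies: Mapping[str, float]
    wobble_s: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WOBBLE_S))

    def __post_init__(self) -> None:
        for a, n in self.copies.items():
            if len(a) != 3 or set(a.upper()) - set(_BASES):
                raise ValueError(f"invalid anticodon {a!r}")
            if n < 0:
                raise ValueError("copy numbers must be >= 0")

    def n(self, anticodon: str) -> float:
        return float(self.copies.get(anticodon, 0.0))

    def absolute_adaptiveness(self) -> dict[str, float]:
        """Per-codon W = sum over decoding anticodons of (1 - s) * copies.

        Watson-Crick pairing plus the standard wobble rules: G34:U3, I:C,
        I:A (inosine from A34), U34:G3, and the bacterial lysidine pathway
        for AUA.  Raises if no sense codon is decodable.
        """
        s = self.wobble_s
        W: dict[str, float] = {}
        for codon in _SENSE_CODONS:
            wc = _revcomp(codon)            # Watson-Crick anticodon
            third = codon[2]
            w = self.n(wc)
            head = wc[1:]                   # positions 35,36 of the anticodon
            if third == "T":                # also read by G34 (G:U wobble)
                w += (1 - s["G:U"]) * self.n("G" + head)
            elif third == "C":              # also read by I34 (written A)
                w += (1 - s["I:C"]) * self.n("A" + head)
            elif third == "A":              # I:A wobble, very weak
                w += (1 - s["I:A"]) * self.n("A" + head)
            elif third == "G":              # U34:G wobble
                w += (1 - s["U:G"]) * self.n("T" + head)
            W[codon] = w
        # bacterial special case: AUA (Ile) is read by lysidine-modified
        # tRNA(CAT), not by its Watson-Crick anticodon TAT
        W["ATA"] = (1 - s["L:A"]) * self.n("CAT") + (1 - s["I:A"]) * self.n("AAT")
        if all(w == 0 for w in W.values()):
            raise ValueError("no sense codon is decoded by any tRNA in the table")
        return W

    def relative_weights(self) -> dict[str, float]:
        """W / max(W), with zero-W codons assigned the geometric mean of
        the nonzero weights (standard tAI convention)."""
        W = self.absolute_adaptiveness()
        top = max(W.values())
        rel = {c: w / top for c, w in W.items()}
        nonzero = [w for w in rel.values() if w > 0]
        gm = math.exp(np.mean(np.log(nonzero)))
        return {c: (w if w > 0 else gm) for c, w in rel.items()}


def compute_tai(seq_or_codons, trna: TRNACopyTable):
    """tRNA adaptation index: geometric mean of per-codon relative weights.

    Stop codons are excluded.  Returns ``(tai, per_codon_weights)``.
    """
    if isinstance(seq_or_codons, CodingSequence):
        codons: Sequence[str] = seq_or_codons.sense_codons
    elif isinstance(seq_or_codons, str):
        s = seq_or_codons.upper()
        codons = [s[i:i + 3] for i in range(0, len(s) - len(s) % 3, 3)]
    else:
        codons = [c.upper() for c in seq_or_codons]
    rel = trna.relative_weights()
    included = [c for c in codons if c in rel]
    if not included:
        raise ValueError("no sense codons for tAI")
    w = np.array([rel[c] for c in included])
    return float(np.exp(np.mean(np.log(w)))), w


# ---------------------------------------------------------------------------
# per-mutation covariates
# ---------------------------------------------------------------------------

def delta_metrics(cds: CodingSequence, mut: PointMutation,
                  usage: CodonUsageTable, trna: TRNACopyTable) -> dict[str, float]:
    """Per-mutation covariates: ΔCAI, ΔtAI, codon index, distance from start.

    Deltas are mutant-CDS metric minus reference-CDS metric.  Nonsense
    mutations are rejected (no complete mutant protein).
    """
    mclass = classify_mutation(cds, mut)
    if mclass == MutationClass.NONSENSE:
        raise ValueError("delta metrics are undefined for nonsense mutations")
    mutant = cds.with_substitution(mut.cds_position, mut.alt_base)
    cai_ref, _ = compute_cai(cds, usage)
    cai_mut, _ = compute_cai(mutant, usage)
    tai_ref, _ = compute_tai(cds, trna)
    tai_mut, _ = compute_tai(mutant, trna)
    return {
        "class": mclass,
        "delta_cai": cai_mut - cai_ref,
        "delta_tai": tai_mut - tai_ref,
        "codon_index": mut.codon_index,
        "distance_from_start_nt": mut.cds_position - 1,
    }


@dataclass(frozen=True)
class MrnaWindow:
    """A folding window centred on a mutated base, with truncation flags."""

    reference: str
    mutant: str
    start: int             # 1-based CDS coordinate of the first window base
    mutation_offset: int   # 0-based index of the mutated base in the window
    truncated_left: bool
    truncated_right: bool


def extract_mrna_window(cds: CodingSequence, mut: PointMutation,
                        width: int = 42) -> MrnaWindow:
    """Reference and mutant sequence windows of ``width`` nt centred on the mutation.

    For even widths the mutated base sits immediately right of centre:
    positions ``[p - width/2, p + width/2 - 1]`` in CDS coordinates (so a
    42-nt window at p=100 covers 79-120).  Flanking sequence is used when
    available; otherwise the window is truncated and flagged.
    """
    if width % 2 != 0:
        raise ValueError("window width must be even")
    if cds.seq[mut.cds_position - 1] != mut.ref_base:
        raise ReferenceMismatchError("reference base mismatch")
    half = width // 2
    full = cds.flank5 + cds.seq + cds.flank3
    p0 = len(cds.flank5) + mut.cds_position - 1    # 0-based in `full`
    lo = p0 - half
    hi = p0 + half                                  # exclusive
    trunc_left = lo < 0
    trunc_right = hi > len(full)
    lo_c, hi_c = max(lo, 0), min(hi, len(full))
    ref_win = full[lo_c:hi_c]
    offset = p0 - lo_c
    mut_win = ref_win[:offset] + mut.alt_base + ref_win[offset + 1:]
    return MrnaWindow(
        reference=ref_win, mutant=mut_win,
        start=lo_c - len(cds.flank5) + 1, mutation_offset=offset,
        truncated_left=trunc_left, truncated_right=trunc_right)


# ---------------------------------------------------------------------------
# translational-ramp test
# ---------------------------------------------------------------------------

@dataclass
class RampTestResult:
    """Rare-codon enrichment near the start codon, tested two ways."""

    slope: float
    adj_r_squared: float
    p_slope: float
    first50_mean: float | None
    rest_mean: float | None
    p_group: float | None
    n_codons: int

    def significant_ramp(self, alpha: float = 0.05) -> bool:
        """A ramp means *lower* weights early: negative slope, small p."""
        return self.slope < 0 and self.p_slope < alpha


def ramp_test(cds: CodingSequence, table, B: int = 10_000,
              seed: int | None = 0, first_n: int = 50) -> RampTestResult:
    """Test whether early codons are enriched for rare (low-weight) codons.

    Fits per-codon adaptiveness weight against codon index (permutation-of-
    residuals p for the slope) and contrasts the first ``first_n`` codons
    against the remainder with a pooled-variance t-test.  The start codon is
    included; the terminal stop is not.
    """
    from .permreg import PermutationOLS, group_ttest

    if isinstance(table, CodonUsageTable):
        rel = table.weights
    elif isinstance(table, TRNACopyTable):
        rel = table.relative_weights()
    else:
        raise TypeError("table must be a CodonUsageTable or TRNACopyTable")
    codons = cds.sense_codons
    idx = np.array([i + 1 for i, c in enumerate(codons) if c in rel], dtype=float)
    w = np.array([rel[c] for c in codons if c in rel])

    res = PermutationOLS(w, idx[:, None], exog_names=["codon_index"]).fit(B=B, seed=seed)
    first = w[idx <= first_n]
    rest = w[idx > first_n]
    if len(rest) < 2 or len(first) < 2:
        warnings.warn(f"gene shorter than {first_n} codons; group comparison skipped")
        f_mean = r_mean = p_group = None
    else:
        t, p_group = group_ttest(first, rest)
        f_mean, r_mean = float(first.mean()), float(rest.mean())
    return RampTestResult(
        slope=float(res.params[1]), adj_r_squared=res.adj_r_squared,
        p_slope=float(res.perm_pvalues["codon_index"]),
        first50_mean=f_mean, rest_mean=r_mean, p_group=p_group,
        n_codons=len(codons))
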