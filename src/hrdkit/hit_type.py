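"""Biallelic (BA) versus monoallelic (MA) hit typing.

Whether both alleles of a gene are inactivated is decided from the local
allele-specific copy-number state (A, B, CN = A + B), the purity-corrected
variant allele frequencies, and the thresholds

    alpha = A / (2 CN)    beta = B / (2 CN)

which assume that at least half the reads of the carrying allele show
the mutation. An alteration is biallelic when any of these holds (first
matching criterion is reported):

1. homozygous deletion (CN = 0);
2. LOH (B = 0, CN > 0) plus a germline mutation;
3. LOH plus a deleterious somatic mutation with VAF >= alpha;
4. a germline plus a deleterious somatic mutation with VAF >= beta;
5. two deleterious somatic mutations (VAF1 >= VAF2) with VAF1 >= alpha
   and VAF2 >= beta.

Otherwise it is monoallelic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VafThresholds:
    """alpha/beta VAF thresholds of one locus state (A, B)."""

    a: int
    b: int

    @property
    def cn(self) -> int:
        return self.a + self.b

    @property
    def alpha(self) -> float:
        if self.cn == 0:
            raise ValidationError("alpha undefined for CN = 0 (homozygous deletion)")
        return self.a / (2 * self.cn)

    @property
    def beta(self) -> float:
        if self.cn == 0:
            raise ValidationError("beta undefined for CN = 0 (homozygous deletion)")
        return self.b / (2 * self.cn)

    @property
    def loh(self) -> bool:
        return self.b == 0 and self.cn > 0


def vaf_thresholds(a: int, b: int) -> VafThresholds:
    """Thresholds for a locus with major copy number ``a``, minor ``b``."""
    if a < b:
        raise ValidationError(f"major copy number {a} < minor {b}")
    if b < 0:
        raise ValidationError("negative copy number")
    return VafThresholds(a, b)


def purity_correct_vaf(vaf: float, purity: float) -> float:
    """Divide the observed VAF by tumor cell content, capped at 1."""
    if purity <= 0 or purity > 1:
        raise ValidationError(f"purity must be in (0, 1], got {purity}")
    if not (0 <= vaf <= 1):
        raise ValidationError(f"VAF must be in [0, 1], got {vaf}")
    return min(1.0, vaf / purity)


@dataclass(frozen=True)
class HitEvent:
    """One deleterious event entering hit typing.

    ``vaf`` is the *raw* VAF (purity correction happens inside the
    classifier); ``locus`` is the (A, B) state at the event position and
    may be omitted when a gene-level locus is supplied instead.
    """

    origin: str  # "germline" | "somatic"
    vaf: float | None = None
    locus: tuple[int, int] | None = None


@dataclass(frozen=True)
class HitCall:
    hit_type: str  # "BA" | "MA"
    criterion: int | None  # 1..5, None for MA
    corrected_vafs: tuple[float, ...] = ()


def classify_hit_type(
    events: list[HitEvent],
    locus: tuple[int, int] | None,
    purity: float = 1.0,
    homozygous_deletion: bool = False,
) -> HitCall:
    """Type a gene's deleterious alteration set as BA or MA.

    ``locus`` is the gene-level (A, B) fallback for events without their
    own locus. Criteria are evaluated in the printed order; the first one
    that holds is reported. With per-event loci, each somatic variant is
    compared against the thresholds of its own segment.
    """
    if not events and not homozygous_deletion:
        raise ValidationError("hit typing undefined without a deleterious event")

    def state_of(ev: HitEvent) -> VafThresholds | None:
        st = ev.locus if ev.locus is not None else locus
        return None if st is None else vaf_thresholds(*st)

    # criterion 1: homozygous deletion
    gene_state = vaf_thresholds(*locus) if locus is not None else None
    if homozygous_deletion or (gene_state is not None and gene_state.cn == 0):
        return HitCall("BA", 1)

    germline = [e for e in events if e.origin == "germline"]
    somatic = [e for e in events if e.origin == "somatic"]
    corrected = {
        id(e): (purity_correct_vaf(e.vaf, purity) if e.vaf is not None else None)
        for e in somatic
    }

    # criterion 2: LOH and germline mutation
    for e in germline:
        st = state_of(e)
        if st is not None and st.loh:
            return HitCall("BA", 2)

    # criterion 3: LOH and deleterious somatic mutation with VAF >= alpha
    for e in somatic:
        st = state_of(e)
        v = corrected[id(e)]
        if st is not None and st.loh and v is not None and v >= st.alpha:
            return HitCall("BA", 3, (v,))

    # criterion 4: germline and deleterious somatic mutation with VAF >= beta
    if germline:
        for e in somatic:
            st = state_of(e)
            v = corrected[id(e)]
            if st is not None and st.cn > 0 and v is not None and v >= st.beta:
                return HitCall("BA", 4, (v,))

    # criterion 5: two deleterious somatic mutations, VAF1 >= alpha, VAF2 >= beta
    with_vaf = [e for e in somatic if corrected[id(e)] is not None and state_of(e) is not None]
    ordered = sorted(with_vaf, key=lambda e: -corrected[id(e)])
    for i, e1 in enumerate(ordered):
        for e2 in ordered[i + 1 :]:
            v1, v2 = corrected[id(e1)], corrected[id(e2)]
            st1, st2 = state_of(e1), state_of(e2)
            if st1.cn > 0 and st2.cn > 0 and v1 >= st1.alpha and v2 >= st2.beta:
                return HitCall("BA", 5, (v1, v2))

    return HitCall("MA", None, tuple(v for v in corrected.values() if v is not None))
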