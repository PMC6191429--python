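"""Effect-allele alignment and phenotype harmonization into a test matrix.

Association results arrive from several cohorts and from external GWAS
summary statistics, each potentially reporting a SNP on either allele and
either strand, and each naming phenotypes in its own vocabulary.  This
module (a) rewrites every record onto a per-SNP reference effect allele,
negating betas and mapping frequencies for flipped records, and (b) groups
records by harmonized phenotype into the meta-analysis test matrix, keeping
the exact total test count for downstream multiple-testing control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from metaphewas._errors import AlleleMismatchError, ConfigError
from metaphewas.assoc import AssociationRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: below this distance from 0.5, a palindromic SNP's frequency cannot
#: distinguish strands
PALINDROME_EAF_MARGIN = 0.08


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass(frozen=True)
class ReferenceAllele:
    """Reference orientation for one SNP; ``eaf`` is needed only for palindromes."""

    effect_allele: str
    other_allele: str
    eaf: float | None = None


@dataclass
class AlignmentResult:
    records: list[AssociationRecord]
    flipped: list[str] = field(default_factory=list)  # "<snp>@<cohort>:<endpoint>"
    palindromic: list[str] = field(default_factory=list)
    unresolved: list[AssociationRecord] = field(default_factory=list)


def _align_one(
    rec: AssociationRecord, ref: ReferenceAllele
) -> tuple[AssociationRecord | None, bool, bool]:
    """Returns (aligned record or None if unresolvable, flipped?, palindromic?)."""
    ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
    rea, roa = ref.effect_allele.upper(), ref.other_allele.upper()

    if is_palindromic(rea, roa):
        # letters alone cannot orient a palindromic SNP: use frequencies
        if {ea, oa} != {rea, roa}:
            raise AlleleMismatchError(
                f"{rec.snp_id}: alleles {ea}/{oa} irreconcilable with reference {rea}/{roa}"
            )
        if (
            ref.eaf is None
            or abs(rec.eaf - 0.5) <= PALINDROME_EAF_MARGIN
            or abs(ref.eaf - 0.5) <= PALINDROME_EAF_MARGIN
        ):
            return None, False, True
        # flip when the record's effect-allele frequency sits on the opposite
        # side of 0.5 from the reference effect-allele frequency
        flip = (rec.eaf > 0.5) != (ref.eaf > 0.5)
        out = rec.flipped() if flip else rec
        if out.effect_allele.upper() != rea:
            # express on the reference letters (same strand ambiguity is moot)
            out = AssociationRecord(
                **{
                    **out.__dict__,
                    "effect_allele": ref.effect_allele,
                    "other_allele": ref.other_allele,
                }
            )
        return out, flip, True

    if (ea, oa) == (rea, roa):
        return rec, False, False
    if (ea, oa) == (roa, rea):
        return rec.flipped(), True, False
    cea, coa = COMPLEMENT.get(ea, "?"), COMPLEMENT.get(oa, "?")
    if (cea, coa) == (rea, roa):
        out = AssociationRecord(
            **{**rec.__dict__, "effect_allele": rea, "other_allele": roa}
        )
        return out, False, False
    if (cea, coa) == (roa, rea):
        out = AssociationRecord(
            **{**rec.__dict__, "effect_allele": roa, "other_allele": rea}
        ).flipped()
        return out, True, False
    raise AlleleMismatchError(
        f"{rec.snp_id}: alleles {ea}/{oa} irreconcilable with reference {rea}/{roa}"
    )


def align_effect_alleles(
    records: Iterable[AssociationRecord],
    reference: Mapping[str, ReferenceAllele | tuple],
) -> AlignmentResult:
    """Express every record on its SNP's reference effect allele.

    Flipped records get beta negated and eaf mapped to 1-eaf; se and p are
    untouched.  Strand-complement reports are normalised to the reference
    letters.  Palindromic (A/T, C/G) SNPs are oriented by allele frequency
    only when both the record's and the reference's effect-allele frequency
    are at least ``PALINDROME_EAF_MARGIN`` away from 0.5; otherwise the
    record lands in ``unresolved`` and is excluded from the aligned list.
    """
    result = AlignmentResult(records=[])
    for rec in records:
        if rec.snp_id not in reference:
            raise AlleleMismatchError(f"no reference orientation for SNP {rec.snp_id}")
        ref = reference[rec.snp_id]
        if not isinstance(ref, ReferenceAllele):
            ref = ReferenceAllele(*ref)
        aligned, flipped, palin = _align_one(rec, ref)
        tag = f"{rec.snp_id}@{rec.cohort_id}:{rec.endpoint_label}"
        if palin:
            result.palindromic.append(tag)
        if aligned is None:
            result.unresolved.append(rec)
            continue
        if flipped:
            result.flipped.append(tag)
        result.records.append(aligned)
    return result


# ---------------------------------------------------------------------------
# test matrix
# ---------------------------------------------------------------------------


@dataclass
class TestMatrix:
    """The complete set of hypothesis tests for one meta-PheWAS run.

    ``mapped_groups`` maps (snp_id, harmonized_id) -> one record per
    contributing source (>= 2 sources each); ``singletons`` holds
    (snp_id, cohort_id, endpoint_label) tests that stand alone.  ``n_tests``
    is the exact count consumed by multiple-testing control.
    """

    mapped_groups: dict[tuple[str, str], list[AssociationRecord]]
    singletons: list[AssociationRecord]
    selection_log: list[dict]
    n_tests: int

    def all_tests(self) -> list[tuple[str, str, list[AssociationRecord]]]:
        """Uniform view: (snp_id, test label, records)."""
        out = [
            (snp, phe, recs) for (snp, phe), recs in sorted(self.mapped_groups.items())
        ]
        out.extend(
            (r.snp_id, f"{r.cohort_id}:{r.endpoint_label}", [r])
            for r in self.singletons
        )
        return out


def build_test_matrix(
    records: Iterable[AssociationRecord],
    mapping: pd.DataFrame,
    known_cohorts: set[str] | None = None,
) -> TestMatrix:
    """Group aligned records into mapped meta-analysis groups and singletons.

    ``mapping`` has columns (cohort_id, endpoint_label, harmonized_id).
    External GWAS records (any cohort_id absent from the cohort files, e.g.
    "GWAS") count as one more source toward the >= 2-source rule when their
    endpoint label appears in the mapping or equals a harmonized id.  When a
    cohort contributes several endpoints to one harmonized id, the endpoint
    with the most cases is selected (ties: lexicographically smallest label)
    and the alternates are logged.
    """
    required = {"cohort_id", "endpoint_label", "harmonized_id"}
    if not required.issubset(mapping.columns):
        raise ConfigError(f"mapping table must have columns {sorted(required)}")
    if mapping.duplicated(subset=["cohort_id", "endpoint_label"]).any():
        raise ConfigError("mapping table has duplicate (cohort_id, endpoint_label) rows")
    if known_cohorts is not None:
        unknown = set(mapping.cohort_id.astype(str)) - set(known_cohorts)
        if unknown:
            raise ConfigError(f"mapping references unknown cohort(s): {sorted(unknown)}")

    map_lookup: dict[tuple[str, str], str] = {
        (str(r.cohort_id), str(r.endpoint_label)): str(r.harmonized_id)
        for r in mapping.itertuples(index=False)
    }
    harmonized_ids = set(map_lookup.values())

    grouped: dict[tuple[str, str], list[AssociationRecord]] = {}
    loose: list[AssociationRecord] = []
    for rec in records:
        hid = map_lookup.get((rec.cohort_id, rec.endpoint_label))
        if hid is None and rec.endpoint_label in harmonized_ids:
            # external summary sources report harmonized ids directly
            hid = rec.endpoint_label
        if hid is None:
            loose.append(rec)
        else:
            grouped.setdefault((rec.snp_id, hid), []).append(rec)

    mapped_groups: dict[tuple[str, str], list[AssociationRecord]] = {}
    singletons: list[AssociationRecord] = list(loose)
    selection_log: list[dict] = []
    for key, recs in grouped.items():
        per_source: dict[str, AssociationRecord] = {}
        for source in sorted({r.cohort_id for r in recs}):
            candidates = sorted(
                (r for r in recs if r.cohort_id == source),
                key=lambda r: (-r.n_cases, r.endpoint_label),
            )
            per_source[source] = candidates[0]
            for alt in candidates[1:]:
                selection_log.append(
                    {
                        "snp_id": key[0],
                        "harmonized_id": key[1],
                        "cohort_id": source,
                        "selected": candidates[0].endpoint_label,
                        "dropped": alt.endpoint_label,
                        "reason": "one endpoint per cohort per phenotype",
                    }
                )
        chosen = list(per_source.values())
        if len(chosen) >= 2:
            mapped_groups[key] = chosen
        else:
            singletons.extend(chosen)

    n_tests = len(mapped_groups) + len(singletons)
    return TestMatrix(
        mapped_groups=mapped_groups,
        singletons=singletons,
        selection_log=selection_log,
        n_tests=n_tests,
    )
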