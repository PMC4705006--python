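"""Organism catalog and the common-commensal list.

A blood-culture isolate is either a recognized pathogen or a common skin
commensal.  Commensals (coagulase-negative staphylococci and friends) are
frequent blood-culture contaminants, so a single commensal-positive draw is
never accepted as an infection by the detection rules; corroboration across
draws plus clinical signs is required.

The commensal status of an isolate is determined solely by membership of its
organism code in the configured commensal set, which defaults to an
NHSN-style common-commensal list.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OrganismIsolate",
    "ORGANISM_CATALOG",
    "DEFAULT_COMMENSAL_CODES",
    "isolate",
    "isolates_from_codes",
]


@dataclass(frozen=True, order=True)
class OrganismIsolate:
    """One organism identified in a culture specimen."""

    organism_code: str
    genus_species: str
    commensal: bool


#: code -> genus/species label.  Pathogens first, then common skin commensals.
ORGANISM_CATALOG: dict[str, str] = {
    # recognized pathogens
    "ECOLI": "Escherichia coli",
    "KPNEU": "Klebsiella pneumoniae",
    "SAURE": "Staphylococcus aureus",
    "PAERU": "Pseudomonas aeruginosa",
    "ABAUM": "Acinetobacter baumannii",
    "EFAEC": "Enterococcus faecalis",
    "EFAEM": "Enterococcus faecium",
    "CALBI": "Candida albicans",
    "SMARC": "Serratia marcescens",
    "ENTCL": "Enterobacter cloacae",
    # common skin commensals (NHSN-style)
    "CONS": "Staphylococcus epidermidis",
    "MICRO": "Micrococcus luteus",
    "CORYN": "Corynebacterium striatum",
    "BACIL": "Bacillus cereus",
    "CUTIB": "Cutibacterium acnes",
    "VIRST": "Streptococcus mitis",
    "AEROC": "Aerococcus viridans",
}

#: Default common-commensal codes: coagulase-negative staphylococci,
#: Micrococcus, Corynebacterium (non-diphtheriae), Bacillus (non-anthracis),
#: Cutibacterium, viridans-group streptococci, Aerococcus.
DEFAULT_COMMENSAL_CODES: frozenset[str] = frozenset(
    {"CONS", "MICRO", "CORYN", "BACIL", "CUTIB", "VIRST", "AEROC"}
)


def isolate(code: str, commensal_codes: frozenset[str] = DEFAULT_COMMENSAL_CODES) -> OrganismIsolate:
    """Build an isolate from an organism code using the catalog.

    Unknown codes are accepted (the catalog is open-world, as hospital
    dictionaries are) and treated as non-commensal pathogens unless listed in
    ``commensal_codes``.
    """
    code = code.strip()
    if not code:
        raise ValueError("empty organism code")
    name = ORGANISM_CATALOG.get(code, code)
    return OrganismIsolate(code, name, code in commensal_codes)


def isolates_from_codes(
    field: str, commensal_codes: frozenset[str] = DEFAULT_COMMENSAL_CODES
) -> tuple[OrganismIsolate, ...]:
    """Parse a pipe-separated organism-code field; '' means no growth."""
    field = (field or "").strip()
    if not field:
        return ()
    return tuple(isolate(tok, commensal_codes) for tok in field.split("|"))
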