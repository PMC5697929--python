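"""Mini-language for survival/detection model formulas.

Models are written in the compact capture-recapture notation
``Phi[season + migr].P[migr]`` (the Greek ``Φ`` is accepted as a synonym for
``Phi``): the bracketed terms list the additive factors entering the logit
linear predictor of survival (Phi) and detection (P).  ``[.]`` denotes an
intercept-only sub-model.

Recognised factors (all two-level, treatment-coded):

========  =====================================  =========
token     factor                                 reference
========  =====================================  =========
season    season type (summer / winter)          summer
migr      migratory strategy (resident/migrant)  resident
sex       sex (female / male)                    female
juv, ad   age at capture (adult / juvenile);     adult
          either token (or both) selects the
          single age factor
t         occasion/interval (fully time-varying)  first
========  =====================================  =========
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ModelSpec",
    "parse_model_spec",
    "format_model_spec",
    "count_parameters",
    "TABLE_MODELS",
]

#: canonical factor order in formatted formulas and design matrices
PHI_FACTOR_ORDER = ("season", "migr", "sex", "age", "t")
P_FACTOR_ORDER = ("migr", "season", "t")

_TOKEN_ALIASES = {
    "season": "season",
    "migr": "migr",
    "migr.": "migr",
    "migration": "migr",
    "strategy": "migr",
    "sex": "sex",
    "juv": "age",
    "ad": "age",
    "age": "age",
    "t": "t",
    "time": "t",
    "occasion": "t",
    ".": None,  # intercept only
}


class FormulaError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic model: additive factors for survival and detection."""

    phi_terms: frozenset = field(default_factory=frozenset)
    p_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        bad = set(self.phi_terms) - set(PHI_FACTOR_ORDER)
        if bad:
            raise FormulaError(f"unknown survival factor(s): {sorted(bad)}")
        bad = set(self.p_terms) - set(P_FACTOR_ORDER)
        if bad:
            raise FormulaError(f"unknown detection factor(s): {sorted(bad)}")

    def __str__(self) -> str:
        return format_model_spec(self)


def _parse_terms(body: str, which: str) -> frozenset:
    body = body.strip()
    if body in ("", "."):
        return frozenset()
    terms = set()
    for raw in body.split("+"):
        tok = raw.strip().lower()
        if tok not in _TOKEN_ALIASES:
            tok = tok.rstrip(".")
        if tok not in _TOKEN_ALIASES:
            raise FormulaError(f"unknown factor token {raw.strip()!r} in {which} terms")
        mapped = _TOKEN_ALIASES[tok]
        if mapped is not None:
            terms.add(mapped)
    return frozenset(terms)


_FORMULA_RE = re.compile(
    r"^\s*(?:Φ|Phi|phi|PHI)\s*\[(?P<phi>[^\]]*)\]\s*\.\s*(?:P|p)\s*\[(?P<p>[^\]]*)\]\s*$"
)


def parse_model_spec(text: str) -> ModelSpec:
    """Parse ``"Phi[season + migr].P[migr]"`` into a :class:`ModelSpec`.

    Tolerates the stray trailing dots and capitalisation variants found in
    published model tables; ``format(parse(s))`` canonicalises ``s``.
    """
    m = _FORMULA_RE.match(text)
    if m is None:
        raise FormulaError(
            f"cannot parse model formula {text!r}; expected 'Phi[...].P[...]'"
        )
    phi = _parse_terms(m.group("phi"), "survival")
    p = _parse_terms(m.group("p"), "detection")
    if not p <= set(P_FACTOR_ORDER):
        raise FormulaError(f"detection terms {sorted(p)} not supported")
    return ModelSpec(phi_terms=phi, p_terms=p)


def format_model_spec(spec: ModelSpec, *, unicode_phi: bool = False) -> str:
    """Canonical text form of a model spec."""
    phi_sym = "Φ" if unicode_phi else "Phi"

    def fmt(terms, order):
        ordered = [f for f in order if f in terms]
        return " + ".join(ordered) if ordered else "."

    return (
        f"{phi_sym}[{fmt(spec.phi_terms, PHI_FACTOR_ORDER)}]"
        f".P[{fmt(spec.p_terms, P_FACTOR_ORDER)}]"
    )


def count_parameters(spec: ModelSpec, n_occasions: int | None = None) -> int:
    """Number of estimated coefficients K.

    Each sub-model contributes an intercept plus one coefficient per
    additional two-level factor; the fully time-varying ``t`` factor
    contributes ``n_intervals - 1`` (survival) or ``n_occasions - 2``
    (detection) coefficients and requires ``n_occasions``.
    """

    def side(terms, n_time_levels):
        k = 1
        for f in terms:
            if f == "t":
                if n_occasions is None:
                    raise FormulaError("time-varying factor requires n_occasions")
                k += n_time_levels - 1
            else:
                k += 1
        return k

    n = n_occasions or 0
    return side(spec.phi_terms, n - 1) + side(spec.p_terms, n - 1)


#: the candidate model set for the seasonal-survival analysis: all additive
#: combinations of season, strategy, sex and age on survival crossed with
#: strategy / season / constant detection that appear in the published
#: 16-row comparison.  One duplicated row (Phi[season+sex].P[.], printed
#: twice with inconsistent parameter counts) is represented once.
TABLE_MODELS = (
    "Phi[season + migr].P[migr]",
    "Phi[season + migr + sex].P[migr]",
    "Phi[season].P[migr]",
    "Phi[season + age].P[migr]",
    "Phi[migr].P[migr]",
    "Phi[.].P[migr]",
    "Phi[sex].P[migr]",
    "Phi[season + migr].P[season]",
    "Phi[season].P[season]",
    "Phi[season + migr + sex].P[season]",
    "Phi[season + sex].P[.]",
    "Phi[season + migr].P[.]",
    "Phi[season + age].P[.]",
    "Phi[season + migr + sex].P[.]",
    "Phi[.].P[season]",
)
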