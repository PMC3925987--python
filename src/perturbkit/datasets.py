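"""Packaged hypothetical populations.

Five four-stratum populations are shipped as CSV fixtures: two confounded
ones (positive and negative confounding, where exposure prevalence and
unexposed disease risk move together resp. oppositely across the strata of
the unmeasured factor) and three unconfounded ones (U associated with
neither exposure nor disease, with disease only, or with exposure only).
They are the standing examples used throughout the tests and simulations.
"""

from __future__ import annotations

from importlib import resources

from .population import StratifiedPopulation

__all__ = ["available_populations", "load_population"]

_FIXTURES = (
    "table1_positive",
    "table1_negative",
    "table2_neither",
    "table2_noE",
    "table2_noD",
)


def available_populations() -> tuple[str, ...]:
    """Names accepted by :func:`load_population`."""
    return _FIXTURES


def load_population(name: str) -> StratifiedPopulation:
    """Load one of the packaged stratified populations by name."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown population {name!r}; available: {', '.join(_FIXTURES)}"
        )
    from .io import read_population  # deferred: io imports population

    ref = resources.files("perturbkit.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        pop = read_population(path)
    return StratifiedPopulation(pop.m, pop.p, pop.r_u, pop.rr, name=name)
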