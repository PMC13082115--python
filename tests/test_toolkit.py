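"""Generator contract, round-trip checker, priority race."""

import math

import pytest

from rxnscript import (
    GeneratorConfig, generate_model, parse_document, priority_race,
    roundtrip_check,
)


def test_empty_config_gives_empty_model_text():
    cfg = GeneratorConfig(seed=1, n_species=0, n_reactions=0)
    assert generate_model(cfg) == ""
    model, diags = parse_document(generate_model(cfg))
    assert not diags and not model.symbols


def test_fbc_features_present_when_enabled():
    cfg = GeneratorConfig(seed=7, n_species=5, n_reactions=4, fbc=True)
    text = generate_model(cfg)
    assert "maximize" in text
    assert "<= J0 <=" in text  # chained flux-bound inequality


def test_generator_is_deterministic():
    cfg = GeneratorConfig(seed=11, n_species=4, n_reactions=3,
                          events=True, distrib=True, layout=True)
    assert generate_model(cfg) == generate_model(cfg)


def test_generated_models_parse_cleanly_across_seeds():
    for seed in range(120):
        cfg = GeneratorConfig(
            seed=seed, n_species=2 + seed % 5, n_reactions=1 + seed % 4,
            events=bool(seed & 1), rules=bool(seed & 2),
            constraints=bool(seed & 4), fbc=bool(seed & 8),
            distrib=bool(seed & 16), layout=bool(seed & 32),
            annotations=bool(seed & 64), named_stoich=bool(seed % 3 == 0),
            substance_only=bool(seed % 5 == 0))
        _, diags = parse_document(generate_model(cfg))
        assert not [d for d in diags if d.severity == "error"], (seed, diags)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(n_species=-1)
    with pytest.raises(ValueError):
        GeneratorConfig(max_math_depth=9)


def test_roundtrip_check_passes_on_simple_reaction():
    assert roundtrip_check("S1 -> S2; k1*S1").passed


def test_roundtrip_check_reports_parse_failures():
    report = roundtrip_check("§ nonsense §")
    assert not report.passed and report.diagnostics


def test_roundtrip_check_on_printed_statement_corpus():
    """Statements of each kind survive the full text→SBML→text pipeline."""
    listings = [
        "S1 -> S2; k1*S1",
        'S1 -> S2; k1*S1\nS1 is "http://identifiers.org/CHEBI:17234"\n'
        'model notes "Markdown **context**"',
        "R1: A -> \nR2: B -> \n0 <= R1 <= 1000\nmaximize R1 + R2",
        "ka = lognormal(0.1, 0.25)",
        "E0: at time > 2 and x < 1, priority = uniform(0,1): x = 3\n"
        "E1: at time > 2 and x < 1, priority = uniform(0,2): x = 5",
        "x = 1\nx.mean = 10\nx.standardDeviation = 2",
        "A -> B\nmodel.layout = on\nA.position = {50, 40}\nA.size = {80, 40}\n"
        "B.position = {200, 40}\nB.size = {80, 40}",
        "G' = -0.1*G\nH := rateOf(G)",
        "A1: 0 = S1 + S2\nS1 -> ; k*S1\nS2 -> ; k*S2",
        "substanceOnly S1\nS1 = 10\nS1 -> ; k*S1",
        "J0: n L -> RL; k*L^n\nn = 3",
        "10 < J2 < 50",
    ]
    for text in listings:
        report = roundtrip_check(text)
        assert report.passed, (text, report.summary())


def test_priority_race_degenerate_and_analytic():
    assert priority_race(1, seed=5) in (0.0, 1.0)
    with pytest.raises(ValueError):
        priority_race(0, seed=1)


def test_priority_race_converges_to_three_quarters():
    """|p̂ − 3/4| stays within 4 binomial standard errors as n grows."""
    for n in (1_000, 10_000):
        frac = priority_race(n, seed=2)
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(frac - 0.75) < 4 * se
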