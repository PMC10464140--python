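"""Shared fixtures: one synthetic locus and a few called scenarios, built
once per session because read placement dominates the runtime."""

from __future__ import annotations

import pytest

from paraloci.breakpoint_caller import call_sample
from paraloci.synthetic_data import (
    LocusParams,
    ReadSimParams,
    apply_deletion,
    apply_transposition,
    generate_locus,
    simulate_reads,
)

LOCUS_SEED = 3


@pytest.fixture(scope="session")
def locus_truth():
    """Default-architecture synthetic locus with exact truth."""
    return generate_locus(LocusParams(seed=LOCUS_SEED))


@pytest.fixture(scope="session")
def locus(locus_truth):
    return locus_truth[0]


@pytest.fixture(scope="session")
def truth(locus_truth):
    return locus_truth[1]


def engineer(locus, truth, label: str, seed: int):
    """One haploid for an allele letter (on its catalog background) or a
    plain haplotype kind."""
    if label in ("REF", "T2_2", "T3_0"):
        return apply_transposition(locus, label)
    spec = truth.deletion_specs[label]
    bg = spec.background if spec.background in ("REF", "T2_2", "T3_0") else "REF"
    hap, tr = apply_transposition(locus, bg)
    return apply_deletion(hap, spec, locus, seed=seed, truth_in=tr)


def call_scenario(locus, truth, label1, label2, seed, depth=22, **err):
    h1, t1 = engineer(locus, truth, label1, seed + 1)
    h2, t2 = engineer(locus, truth, label2, seed + 2)
    reads = simulate_reads((h1, h2), ReadSimParams(seed=seed, depth=depth, **err))
    paths, regions, genotype = call_sample(reads, locus, truth.planted_psvs)
    return {
        "haploid_truths": (t1, t2),
        "reads": reads,
        "paths": paths,
        "regions": regions,
        "genotype": genotype,
    }


@pytest.fixture(scope="session")
def hom_e_call(locus, truth):
    """Homozygous allele-E sample (deletion on the long-transposition
    background), error-free reads."""
    return call_scenario(locus, truth, "E", "E", seed=9001)


@pytest.fixture(scope="session")
def hom_g_call(locus, truth):
    """Homozygous three-crossover allele-G sample, error-free reads."""
    return call_scenario(locus, truth, "G", "G", seed=9002)
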