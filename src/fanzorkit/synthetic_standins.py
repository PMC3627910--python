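"""Synthetic stand-ins for the published worked-example sequences.

The identity and structure figures quoted for the real element families
(viral Fanzor element pairs 88% identical over their full length, Mariner
pairs ~78-79% identical over their shared 5' kilobase, a 633-residue Fanzor
protein, 33-bp and 18-bp TIR elements, a Helitron2 exemplar) refer to
supplementary sequence files that are not distributed with this package.
Every object built here is *synthetic*: a randomly generated sequence (or
family) constructed at the published regime — same lengths, divergences and
terminal structures — so that the toolkit's detectors and identity
calculations can be exercised end to end. Results on these stand-ins validate
the machinery, not the original sequences.
"""

from __future__ import annotations

import math

import numpy as np

from fanzorkit.seqio import NucSequence, ProtSequence
from fanzorkit.simulate import (
    FamilySpec,
    Helitron2Structure,
    TirStructure,
    _mutate,
    _random_seq,
    make_element,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def divergence_for_pairwise_identity(identity_frac: float) -> float:
    """Per-copy substitution rate giving the target identity between two
    copies independently diverged from a shared ancestor.

    Per-site match probability between two such copies is
    (1-d)^2 + d^2/3; solve for d.
    """
    disc = 4.0 - (16.0 / 3.0) * (1.0 - identity_frac)
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def diverged_pair(seed: int, length: int, divergence: float) -> tuple[NucSequence, NucSequence]:
    """Synthetic pair: a random sequence and a copy diverged one-sidedly.

    Expected identity is 100 * (1 - divergence) percent.
    """
    rng = np.random.default_rng([seed, 101])
    a = _random_seq(rng, length)
    b = _mutate(a, divergence, rng)
    return NucSequence("standin_a", a), NucSequence("standin_b", b)


def diverged_family(
    seed: int, length: int, n_copies: int, rate: float
) -> tuple[NucSequence, list[NucSequence]]:
    """Synthetic family: ancestor plus copies each diverged at ``rate``."""
    rng = np.random.default_rng([seed, 202])
    anc = _random_seq(rng, length)
    copies = [NucSequence(f"copy{i}", _mutate(anc, rate, rng)) for i in range(n_copies)]
    return NucSequence("ancestor", anc), copies


def fragment_and_element(
    seed: int, element_len: int, fragment_len: int, divergence: float
) -> tuple[NucSequence, NucSequence]:
    """Synthetic 5' fragment diverged from the element it derives from."""
    rng = np.random.default_rng([seed, 303])
    elem = _random_seq(rng, element_len)
    frag = _mutate(elem[:fragment_len], divergence, rng)
    return NucSequence("standin_fragment", frag), NucSequence("standin_element", elem)


def fanzor_protein_standin(seed: int, length: int = 633) -> ProtSequence:
    """Synthetic 633-residue Fanzor-like protein with the signature planted
    so that the terminal RD anchor lies in the C-terminal half."""
    rng = np.random.default_rng([seed, 404])
    s = list("".join(rng.choice(list(_AA), size=length)))
    anchors = {220: "D", 371: "T", 372: "S", 375: "C", 378: "C", 389: "C", 392: "C", 398: "R", 399: "D"}
    for pos, res in anchors.items():
        s[pos] = res
    return ProtSequence("fanzor_standin", "".join(s))


def spu1_like_element(seed: int) -> NucSequence:
    """Synthetic 2,100-bp element flanked by 33-bp TIRs (SPu-1 architecture)."""
    return make_element(FamilySpec("spu1_standin", element_len=2100, structure=TirStructure(33)), seed)


def esvi1b_like_element(seed: int) -> NucSequence:
    """Synthetic element flanked by 18-bp TIRs (ESvi-1B architecture)."""
    return make_element(FamilySpec("esvi1b_standin", element_len=1500, structure=TirStructure(18)), seed)


def helitron2_like_element(seed: int) -> NucSequence:
    """Synthetic Helitron2 exemplar (ATIR pair plus hairpins at both ends)."""
    return make_element(
        FamilySpec("helitron2_standin", element_len=1000, structure=Helitron2Structure()), seed
    )
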