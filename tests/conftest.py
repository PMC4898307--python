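import random

import pytest

from guidelink import Association, AssociationSet, DrugTerm, build_vocabulary, normalize_term
from guidelink.synthetic import GeneratorConfig, generate


def make_vocab(entries, stoplist=()):
    """entries: iterable of (surface, source, atc_codes, is_class)."""
    terms = [
        DrugTerm(
            surface=surface,
            normalized=normalize_term(surface),
            concept_id=f"{source}:{i}",
            source=source,
            atc_codes=tuple(codes),
            is_class=is_class,
        )
        for i, (surface, source, codes, is_class) in enumerate(entries)
    ]
    return build_vocabulary([terms], stoplist=stoplist)


def make_assoc(key, condition, source, codes=(), provenance=("x",)):
    return Association(
        drug_key=key,
        condition=condition,
        source=source,
        provenance=frozenset(provenance),
        atc_codes=tuple(codes),
    )


def random_coded_associations(rng: random.Random, side: str, n: int,
                              conditions=("hf", "ihd"), letters="AB"):
    """Random associations over a toy ATC-shaped code space."""
    assocs = {}
    for i in range(n):
        letter = rng.choice(letters)
        l4 = f"{letter}{rng.randrange(3):02d}{rng.choice('AB')}{rng.choice('AB')}"
        level = rng.choice((4, 4, 5, 5, 5))
        code = l4 if level == 4 else f"{l4}{rng.randrange(1, 4):02d}"
        key = f"drug-{code.lower()}" if level == 5 else f"class-{code.lower()}"
        cond = rng.choice(conditions)
        assocs[(key, cond)] = make_assoc(key, cond, side, codes=(code,),
                                         provenance=(f"{side}-{i}",))
    return AssociationSet(associations=tuple(assocs.values()), side=side)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One small synthetic study bundle shared across read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    config = GeneratorConfig(
        seed=11, n_conditions=4, n_level4_classes=4, drugs_per_class=3,
        n_guidelines_per_condition=3,
    )
    return generate(config, out)
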