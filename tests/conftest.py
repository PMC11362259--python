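import numpy as np
import pandas as pd
import pytest

import gesturemorphs as gm
from gesturemorphs.io import default_table_path


@pytest.fixture(scope="session")
def chimp_schema():
    return gm.schema_from_yaml(default_table_path("chimp_schema.yaml"))


@pytest.fixture(scope="session")
def chimp_rulesets(chimp_schema):
    """The transcribed published morph table (115 morphs, 42 actions)."""
    return gm.parse_rule_table(
        default_table_path("chimp_morph_table.csv"), chimp_schema
    )


@pytest.fixture
def small_schema():
    return gm.ModifierSchema(
        modifiers={
            "body_part": frozenset({"Hand", "Foot", "Head"}),
            "repetition": frozenset({"Yes", "No"}),
        },
    )


@pytest.fixture
def small_token_csv(tmp_path):
    path = tmp_path / "tokens.csv"
    path.write_text(
        "token_id,community,signaller_id,gesture_action,body_part,repetition,goal\n"
        "t1,Sonso,s1,Shake,Hand,Yes,Play\n"
        "t2,Sonso,s2,Shake,Foot,No,Travel\n"
        "t3,Waibira,s1,Hit,Head,unknown,Play\n"
    )
    return path


def planted_table(k=3, n=300, seed=0, theta=0.95, **kw):
    """One-action synthetic table with k planted morphs."""
    spec = gm.SyntheticSpec(
        actions=[gm.planted_action_spec("A", n, k=k, seed=seed)],
        theta_def=theta, missing_rate=kw.pop("missing_rate", 0.0),
        unknown_goal_rate=kw.pop("unknown_goal_rate", 0.0),
        seed=seed + 5000, **kw,
    )
    return gm.generate_tokens(spec)
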