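import numpy as np
import pytest

from cogrehab import CTTModel, Profile, ProfileSchema
from cogrehab.io import default_instruments, default_weight_table


@pytest.fixture(scope="session")
def body_schema() -> ProfileSchema:
    """Integer-grid demo schema (age, weight, height)."""
    return ProfileSchema(
        ("age", "weight", "height"),
        ((0, 120, 1), (0, 200, 1), (0, 250, 1)),
    )


@pytest.fixture(scope="session")
def john(body_schema) -> Profile:
    return Profile(body_schema, (20.0, 80.0, 178.0))


@pytest.fixture(scope="session")
def training_schema() -> ProfileSchema:
    """Half-step 1-10 training scale over two cognitive domains."""
    return ProfileSchema.uniform(("memory", "attention"), 1.0, 10.0, 0.5)


@pytest.fixture(scope="session")
def weight_table():
    return default_weight_table()


@pytest.fixture(scope="session")
def instruments():
    return default_instruments()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


def make_task(
    task_id: str = "memory_search",
    kind: str = "search",
    training_weights=None,
    coverage=None,
    contexts=("kitchen",),
    parameters=None,
    nominal_minutes: float = 11.0,
) -> CTTModel:
    return CTTModel(
        id=task_id,
        kind=kind,
        contexts=tuple(contexts),
        coverage=coverage if coverage is not None else {"memory": (30.0, 80.0)},
        training_weights=(
            training_weights if training_weights is not None else {"memory": 1.0}
        ),
        parameters=parameters if parameters is not None else {"targets": (1, 12)},
        nominal_minutes=nominal_minutes,
    )


@pytest.fixture(scope="session")
def two_domain_repo() -> list[CTTModel]:
    """One memory task and one attention task on the training schema."""
    return [
        make_task("memory_search", training_weights={"memory": 1.0}),
        make_task(
            "attention_drive",
            kind="drive",
            training_weights={"attention": 1.0},
            coverage={"attention": (20.0, 90.0)},
            contexts=("transportation",),
            parameters={"obstacles": (1, 20)},
        ),
    ]
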