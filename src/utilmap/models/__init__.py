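"""Model families for the nine mapping algorithms.

``ALL_FAMILIES`` maps the canonical family key to a display label in the
conventional comparison-table order (five direct, four response).
"""

from .base import ConvergenceInfo, read_json
from .direct import (
    DIRECT_FAMILIES,
    DirectMapping,
    DirectResults,
    fit_clad,
    fit_ols_direct,
    fit_tobit,
    fit_two_part,
    predict_direct,
    two_part_combine,
)
from .response import (
    RESPONSE_FAMILIES,
    ItemModel,
    ResponseMapping,
    ResponseResults,
    expected_utility,
    fit_item_model,
    fit_response_mapper,
    modal_state_utility,
    predict_item_distribution,
)

ALL_FAMILIES = {
    "direct_ols_continuous": "Direct OLS Continuous",
    "direct_ols_categorical": "Direct OLS Categorical",
    "direct_tobit": "Direct Tobit",
    "direct_clad": "Direct CLAD",
    "direct_two_part": "Direct 2-part",
    "response_ols_categorical": "Response OLS Categorical",
    "response_ols_continuous": "Response OLS Continuous",
    "response_ologit": "Response ologit",
    "response_mlogit": "Response mlogit",
}


def fit_family(table, family_key: str, cluster: bool = True):
    """Fit one of the nine mapping algorithms by its canonical key."""
    if family_key not in ALL_FAMILIES:
        raise ValueError(
            f"unknown family {family_key!r}; choose from {list(ALL_FAMILIES)}"
        )
    group, _, family = family_key.partition("_")
    if group == "direct":
        if family == "clad":
            return fit_clad(table)
        return DirectMapping(table, family).fit(cluster=cluster)
    return ResponseMapping(table, family).fit()


def load_model(path):
    """Load a serialised model JSON, dispatching on its ``kind`` field."""
    doc = read_json(path)
    if doc.get("kind") == "direct":
        return DirectResults.from_dict(doc)
    if doc.get("kind") == "response":
        return ResponseResults.from_dict(doc)
    raise ValueError(f"not a recognised model document: {path}")
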