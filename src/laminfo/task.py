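"""Visual-search task utilities."""

from __future__ import annotations


def chance_accuracy(set_size: int) -> float:
    """Chance accuracy for oddball search among ``set_size`` array items.

    A guess is correct with probability 1/set_size: 1/6 for a target among
    five distractors, 1/8 for a target among seven.
    """
    if set_size < 2:
        raise ValueError("search array needs at least 2 items")
    return 1.0 / set_size
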