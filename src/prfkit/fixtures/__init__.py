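"""Packaged fixtures: the printed dual-reporter insert sequences, the
Eumycota species tree with the 3'-ORF presence character, and the reporter
simulator's efficiency calibration."""

from __future__ import annotations

import json
from importlib import resources

from ..parsimony import CharacterTree
from ..sequences import NucSequence, read_sequences
from ..simulate import ReporterSpec

__all__ = [
    "fixture_path",
    "reporter_inserts",
    "yip3_character_tree",
    "reporter_calibration",
    "calibrated_reporter_specs",
]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file."""
    return resources.files(__package__) / name


def reporter_inserts() -> dict[str, NucSequence]:
    """The five reporter insert sequences, keyed by construct name."""
    return {s.id: s for s in read_sequences(fixture_path("reporter_inserts.fasta"))}


def yip3_character_tree() -> CharacterTree:
    return CharacterTree.from_files(
        fixture_path("yip3_tree.nwk"), fixture_path("yip3_states.tsv")
    )


def reporter_calibration() -> dict:
    with open(fixture_path("reporter_calibration.json")) as fh:
        return json.load(fh)


def calibrated_reporter_specs(seed: int = 0) -> dict[str, ReporterSpec]:
    """A ReporterSpec per calibrated construct (control: Podo0 baseline)."""
    cal = reporter_calibration()
    return {
        name: ReporterSpec(
            true_efficiency_percent=entry["true_efficiency_percent"],
            n_replicates=cal["n_replicates"],
            cv=cal["cv"],
            base_ratio=cal["base_ratio"],
            bgal_level=cal["bgal_level"],
            seed=seed,
        )
        for name, entry in cal["constructs"].items()
    }
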