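"""Packaged synthetic fixture builders.

These assemble the study-shaped datasets the acceptance checks run on: a
MAG collection mixing complete-operon genomes with annotation-conflicted
and fragmented decoys, and per-lineage whole-genome annotation sets for
pathway completeness scoring. Fixture structure lives in packaged YAML/
code; sequence content is generated at call time from the seed.
"""

from __future__ import annotations

from importlib import resources as importlib_resources

import yaml

from .synthgen import TEMPLATES, Genome, TaxonSpec, build_genome


def load_mag_config(name: str = "mags_tb") -> dict:
    text = (
        importlib_resources.files("diazoscan.resources.configs") / f"{name}.yaml"
    ).read_text()
    return yaml.safe_load(text)


def build_mag_collection(seed: int, name: str = "mags_tb") -> list[Genome]:
    """Build the packaged MAG fixture set (genomes + feature tables +
    three-system annotations + truth)."""
    cfg = load_mag_config(name)
    genomes: list[Genome] = []
    for entry in cfg["genomes"]:
        templates = [TEMPLATES[entry["template"]]]
        if "extra_template" in entry:
            templates.append(TEMPLATES[entry["extra_template"]])
        spec = TaxonSpec(
            taxon_id=entry["id"],
            lineage_label=entry["lineage"],
            diazotroph=True,
            operon_template_id=entry["template"],
            genome_length=int(entry.get("genome_length", cfg.get("genome_length", 40_000))),
        )
        genomes.append(
            build_genome(
                spec,
                templates,
                seed=seed,
                conflict_labels=bool(entry.get("conflict_labels", False)),
                nifh_identity=entry.get("nifh_identity"),
            )
        )
    return genomes


# ---------------------------------------------------------------------------
# whole-genome annotation fixtures for pathway scoring

_CHLOROSOME_MINUS_BCIC = [
    "csmA", "csmB", "csmC", "bchK", "bchU", "bchV",
    "bchQ", "bchR", "bchE", "bchJ", "bciB",
]
_RTCA = ["aclA", "aclB", "korA", "korB", "porA", "porB",
         "frdA", "fumA", "mdh", "sucC", "sucD"]
_WL = ["acsA", "acsB", "acsC", "acsD", "acsE", "fhs", "folD", "metF", "fdhA"]
_SULFATE = ["dsrA", "dsrB", "sat", "aprA", "aprB"]
_RNF = ["rnfA", "rnfB", "rnfC", "rnfD", "rnfE"]


def chlorobi_fixture_symbols() -> list[str]:
    """Gene symbols of the Chlorobi-like fixture genome: every shipped
    chlorosome gene except bciC, a complete rTCA cycle, dsrAB without the
    sulfate-activation genes, and hydrogenase/nitrogenase structural genes."""
    return (
        _CHLOROSOME_MINUS_BCIC
        + _RTCA
        + ["dsrA", "dsrB"]
        + ["hupL", "hupS"]
        + ["nifH", "nifD", "nifK", "glnB"]
    )


def desulfobacterales_fixture_symbols() -> list[str]:
    """Desulfobacterales-like fixture: dissimilatory sulfate reduction, rnf
    complex and Wood-Ljungdahl genes; no methylotrophy."""
    return (
        _SULFATE
        + _RNF
        + _WL
        + ["nifH", "nifD", "nifK", "glnB", "draG", "draT"]
    )


def methylococcales_fixture_symbols() -> list[str]:
    """Methylococcales-like fixture: methylotrophy markers, rnf complex and
    the full accessory nif set."""
    return (
        ["pmoA", "mdh1", "mxaF"]
        + _RNF
        + ["nifH", "nifD", "nifK", "nifQ", "nifZ", "nifU", "nifS", "nifW",
           "nifA", "nifL"]
    )


def pathway_fixture_genomes() -> dict[str, list[str]]:
    return {
        "chlorobi_fixture": chlorobi_fixture_symbols(),
        "desulfobacterales_fixture": desulfobacterales_fixture_symbols(),
        "methylococcales_fixture": methylococcales_fixture_symbols(),
    }
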