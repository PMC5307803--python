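#!/usr/bin/env python
"""Replicate the sensitivity tables (and optionally the PPI bias ROC) on a
real ontology.

The desk-scale test suite exercises this exact pipeline on generated
ontologies; pointing ``--obo`` at a downloaded GO/HPO release reproduces
the full-ontology analysis.  At ``--per-group 20`` the GO run takes tens of
minutes on one core; the published design (sizes 1..55, 100 entities per
size) is a long batch job::

    python scripts/replicate_tables.py --obo go.obo --sizes 1:55 \
        --per-group 20 --seed 1 --out-dir results/go

    # with yeast annotations and interactions on disk:
    python scripts/replicate_tables.py --obo go.obo \
        --gaf gene_associations.sgd.gz --interactions interaction_data.tab \
        --out-dir results/yeast
"""

from __future__ import annotations

import argparse

from ontosim.experiments import DESK_MEASURES
from ontosim.pipeline import RunConfig, run_bias_suite, run_ppi_eval


def build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--obo", required=True, help="OBO 1.2 file (gzip ok)")
    parser.add_argument("--gaf", help="GAF 2.x annotation file (optional)")
    parser.add_argument("--interactions", help="interaction TSV (optional)")
    parser.add_argument("--columns", default="0,1", help="interaction table columns")
    parser.add_argument("--sizes", default="1:55")
    parser.add_argument("--per-group", type=int, default=20)
    parser.add_argument("--depths", default=None, help='e.g. "1:17"')
    parser.add_argument("--size-per-entity", type=int, default=10)
    parser.add_argument("--measures", nargs="*", default=list(DESK_MEASURES))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", required=True)
    return parser


def _parse_range(text: str) -> tuple[int, ...]:
    if ":" in text:
        lo, hi = text.split(":")
        return tuple(range(int(lo), int(hi) + 1))
    return tuple(int(x) for x in text.split(","))


def run(
    obo_path: str,
    out_dir: str,
    sizes=range(1, 56),
    per_group: int = 20,
    depths=None,
    size_per_entity: int = 10,
    measures=DESK_MEASURES,
    seed: int = 1,
    gaf_path: str | None = None,
    interactions_path: str | None = None,
    interaction_cols: tuple[int, int] = (0, 1),
):
    """Size/difference (and optional depth) tables for one ontology."""
    analyses = ["size", "difference"] + (["depth"] if depths else [])
    config = RunConfig(
        out_dir=out_dir,
        seed=seed,
        obo_path=obo_path,
        measures=tuple(measures),
        sizes=tuple(sizes),
        per_group=per_group,
        depths=tuple(depths) if depths else None,
        size_per_entity=size_per_entity,
        analyses=tuple(analyses),
    )
    table = run_bias_suite(config)["table"]
    if gaf_path and interactions_path:
        ppi_config = RunConfig(
            out_dir=str(out_dir) + "_ppi",
            seed=seed,
            obo_path=obo_path,
            gaf_path=gaf_path,
            interactions_path=interactions_path,
            interaction_cols=interaction_cols,
            measures=("gic", "resnik:bma", "resnik:average"),
        )
        ppi = run_ppi_eval(ppi_config)["table"]
        print(ppi.to_string(index=False))
    return table


def main() -> None:
    args = build_parser().parse_args()
    cols = tuple(int(c) for c in args.columns.split(","))
    table = run(
        obo_path=args.obo,
        out_dir=args.out_dir,
        sizes=_parse_range(args.sizes),
        per_group=args.per_group,
        depths=_parse_range(args.depths) if args.depths else None,
        size_per_entity=args.size_per_entity,
        measures=tuple(args.measures),
        seed=args.seed,
        gaf_path=args.gaf,
        interactions_path=args.interactions,
        interaction_cols=(cols[0], cols[1]),
    )
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
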