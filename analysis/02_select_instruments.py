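"""Instrument selection for each MR leg, with per-stage exclusion counts.

Reads the cohorts written by 01_simulate_cohorts.py, harmonizes each
exposure-outcome pair, applies the filter chain (exposure p < 5e-6,
MAF >= 0.01, LD clump r2 < 0.01 in a 10,000 kb window, F > 10; the
outcome-p screen is off because in this strong-effect synthetic world
every valid instrument is outcome-associated through the exposure), and
writes the retained counts and stage-by-stage exclusions.
"""

import argparse
from pathlib import Path

import pandas as pd

from medmr.instruments import InstrumentCriteria, LDMatrix, select_instruments
from medmr.sumstats import harmonize, read_sumstats

CRITERIA = InstrumentCriteria(outcome_p_policy="off")


def main(data: Path = Path("results/data"), out: Path = Path("results")) -> None:
    out.mkdir(parents=True, exist_ok=True)
    traits = {name: read_sumstats(data / f"{name}.tsv")[0]
              for name in ("exposure", "mediator", "outcome")}
    # two-step rule: the mediator's instruments must not act through the
    # exposure, so drop SNPs that qualify as exposure instruments
    p_exp = {r.snp_id: r.pvalue for r in traits["exposure"]}
    traits["mediator_own"] = [r for r in traits["mediator"]
                              if p_exp.get(r.snp_id, 1.0) >= CRITERIA.p_exposure_max]
    ld = LDMatrix.from_file(data / "ld.tsv")
    rows = []
    for exp_name, out_name in [("exposure", "mediator"),
                               ("mediator_own", "outcome"),
                               ("exposure", "outcome")]:
        pairs, hlog = harmonize(traits[exp_name], traits[out_name])
        retained, slog = select_instruments(pairs, CRITERIA, ld=ld)
        counts = {**hlog.stage_counts(), **slog.stage_counts()}
        rows.append({"leg": f"{exp_name}->{out_name}",
                     "n_input": len(traits[exp_name]),
                     "n_retained": len(retained), **counts})
        print(f"{exp_name}->{out_name}: {len(retained)} instruments retained, "
              f"exclusions {counts}")
    pd.DataFrame(rows).fillna(0).to_csv(out / "instrument_selection.tsv",
                                        sep="\t", index=False)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.data, args.out)
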