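"""Two-step mediation decomposition on the synthetic cohorts.

Estimates beta1 (exposure->mediator), beta2 (mediator->outcome, using the
mediator's own instruments) and beta3 (total exposure->outcome) by IVW,
decomposes the total effect by the product of coefficients, and compares
the estimated proportion mediated with the generative truth (10.71% under
the default design). Also prints the decomposition for a pathway whose
coefficient signs disagree, which the reporting rule suppresses.
"""

import argparse
from pathlib import Path

import pandas as pd

from medmr.instruments import InstrumentCriteria, LDMatrix
from medmr.mediation import two_step_mediation
from medmr.pipeline import run_mediation
from medmr.sumstats import read_sumstats

CRITERIA = InstrumentCriteria(outcome_p_policy="off")


def main(data: Path = Path("results/data"), out: Path = Path("results")) -> None:
    out.mkdir(parents=True, exist_ok=True)
    traits = {name: read_sumstats(data / f"{name}.tsv")[0]
              for name in ("exposure", "mediator", "outcome")}
    ld = LDMatrix.from_file(data / "ld.tsv")
    row = run_mediation(traits["exposure"], traits["mediator"], traits["outcome"],
                        criteria=CRITERIA, ld=ld,
                        names=("taxon_synthetic", "ibd_synthetic", "crc_synthetic"))
    table = pd.DataFrame([row])
    table.to_csv(out / "mediation_table.tsv", sep="\t", index=False)
    print("mediation decomposition (IVW legs):")
    print(f"  total effect      {row['total_effect']:+.4f}  (truth -0.5600)")
    print(f"  mediation effect  {row['mediation_effect']:+.4f}  (truth -0.0600)")
    print(f"  direct effect     {row['direct_effect']:+.4f}  (truth -0.5000)")
    print(f"  proportion        {row['mediation_proportion_pct']:.2f}%  (truth 10.71%)")
    print(f"  sign-consistent   {row['consistent']}")

    # a pathway whose mediated and total effects disagree in sign is
    # decomposed but flagged: the reporting rule drops it from the table
    opposed = two_step_mediation(0.4, 0.3, -0.5)
    print("\nsign-opposed example: mediation "
          f"{opposed.mediation_effect:+.3f} vs total {opposed.beta3:+.3f} "
          f"-> consistent={opposed.consistent} (suppressed from report)")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.data, args.out)
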