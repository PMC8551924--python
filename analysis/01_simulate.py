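#!/usr/bin/env python
"""Generate the default synthetic cohort and serialize it under results/run/.

Emulated study conditions: 13 tumor samples on a 136-gene / 2998-probe panel;
arm-level losses on 1p (31%) and 11q (38%), gain on 17q (69%); focal MYCN
amplification (10-40 copies, 23%); a 418-compound single-dose screen with DMSO
and staurosporine controls; ~3.1 somatic variant candidates per sample.
"""

from pathlib import Path

from nbscreen import pipeline_io as io

from _shared import OUT, SEED, run_config


def main() -> None:
    io.configure_logging()
    cohort = io.simulate_stage(run_config(), OUT, SEED)
    n_probes = len(cohort.probe_table)
    n_wells = sum(len(p.wells) for p in cohort.plates)
    print(f"cohort: {cohort.config.n_samples} samples, "
          f"{len(cohort.config.panel)} genes, {n_probes} probes, "
          f"{cohort.config.n_drugs} drugs, {n_wells} wells, "
          f"{len(cohort.variants)} variant candidates")
    print(f"written to {OUT / 'cohort'}")


if __name__ == "__main__":
    main()
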