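#!/usr/bin/env python
"""Generate the seeded synthetic FMT-virome study and write its input files.

Emulates the trial design: 5 healthy donors (sampled pre-FMT only), 3
self-stool controls, 3 responders and 3 non-responders sampled at weeks
0, 3, 6, 12 and 18, sequenced at a constant depth of 1,367,462 reads.
"""

from pathlib import Path

from viromefmt import SimParams, simulate_study, write_fixtures

DATA = Path(__file__).resolve().parent.parent / "data" / "synthetic"


def main() -> None:
    params = SimParams(seed=7)
    study = simulate_study(params)
    write_fixtures(study, DATA)
    n_grouped = len(study.truth.hv_membership)
    print(f"catalog: {len(study.catalog)} contigs "
          f"({n_grouped} in {params.n_hv_groups} HV groups, "
          f"{len(study.truth.singletons)} singletons, "
          f"{len(study.flags_16s)} 16S contaminants)")
    print(f"hit table: {len(study.hits)} similarity hits")
    print(f"samples: {study.counts.values.shape[1]} at depth "
          f"{params.reads_per_sample:,} reads each")
    print(f"planted biomarker HV groups: {study.truth.biomarker_hv_ids}")
    print(f"wrote fixtures to {DATA}")


if __name__ == "__main__":
    main()
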