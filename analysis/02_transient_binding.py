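#!/usr/bin/env python
"""Transient (stopped-flow) substrate-binding analysis and mechanism
discrimination.

Simulates tryptophan-fluorescence quenching traces under an induced-fit
mechanism (ten substrate concentrations, seven replicates, 2% noise), then
runs the full protocol: double-exponential phase analysis per concentration,
observed-rate-law fits for starting estimates, global fits of the induced-fit
and one-step candidates, and discrimination by chi2 plus parameter
constraint.

Writes results/transient_fit.json.
"""

import json
from pathlib import Path

import numpy as np

import lumidyn as ld
from lumidyn.fitting import fit_exponentials, fit_rate_dependence
from lumidyn.synth import KineticDesign, NoiseSpec, gen_kinetic_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 11

TRUE = ld.RateConstantSet(k_plus1=2.0, k_minus1=50.0, k_plus2=30.0, k_minus2=3.0)
DESIGN = KineticDesign(
    S_concentrations=(5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 55.0, 70.0, 85.0, 100.0),
    E0=1.0, n_replicates=7, t_max=0.3, n_points=150,
)


def main() -> None:
    spec = ld.make_mechanism("INDUCED_FIT", TRUE)
    obs = ld.ObservationModel("FLUORESCENCE", f=5.0, a=0.7, b=0.3,
                              mechanism_kind=ld.MechanismKind.INDUCED_FIT)
    ds = gen_kinetic_dataset(spec, obs, DESIGN, NoiseSpec(level=0.02, seed=SEED))
    print(f"simulated {len(ds)} fluorescence traces "
          f"({len(DESIGN.S_concentrations)} concentrations x {DESIGN.n_replicates} "
          "replicates, 2% noise)")

    t = ds.traces[0].time
    S, kf, ks = [], [], []
    for S0 in DESIGN.S_concentrations:
        avg = np.mean([tr.signal for tr in ds if tr.S0 == S0], axis=0)
        ph = fit_exponentials(t, avg, n_phases=2)
        S.append(S0)
        kf.append(ph.k_fast)
        ks.append(ph.k_slow)
    print("double-exponential phases: k_fast "
          f"{kf[0]:.0f}..{kf[-1]:.0f} s^-1, k_slow {ks[0]:.1f}..{ks[-1]:.1f} s^-1")

    rd = fit_rate_dependence(np.array(S), "INDUCED_FIT",
                             k_fast=np.array(kf), k_slow=np.array(ks))
    print(f"rate-law starting estimates: {rd.rates.to_dict()}")

    fr_if = ld.fit_global(
        ds, spec, obs,
        free_params=["k_plus1", "k_minus1", "k_plus2", "k_minus2", "f"],
        starts={**{k: max(v, 0.5) for k, v in rd.rates.to_dict().items()}, "f": 5.0},
    )
    print("global induced-fit estimates "
          f"(truth k+1=2, k-1=50, k+2=30, k-2=3):")
    for k in ("k_plus1", "k_minus1", "k_plus2", "k_minus2"):
        print(f"  {k} = {fr_if.estimates[k]:.3f} +- {fr_if.stderr[k]:.3f}")

    os_spec = ld.make_mechanism("ONE_STEP", ld.RateConstantSet(k_plus1=1.0, k_minus1=20.0))
    os_obs = ld.ObservationModel("FLUORESCENCE", f=5.0, a=0.5,
                                 mechanism_kind=ld.MechanismKind.ONE_STEP)
    fr_os = ld.fit_global(ds, os_spec, os_obs,
                          free_params=["k_plus1", "k_minus1", "a", "f"])
    ratio = fr_os.chi2 / fr_if.chi2
    print(f"one-step chi2 / induced-fit chi2 = {ratio:.2f} "
          "(the one-step model cannot describe the biphasic quenching)")

    OUT.mkdir(exist_ok=True)
    (OUT / "transient_fit.json").write_text(json.dumps({
        "phase_analysis": {"S_uM": S, "k_fast": kf, "k_slow": ks},
        "rate_law_starts": rd.rates.to_dict(),
        "induced_fit": {"estimates": fr_if.estimates, "stderr": fr_if.stderr,
                        "chi2": fr_if.chi2, "dof": fr_if.dof},
        "one_step": {"chi2": fr_os.chi2, "dof": fr_os.dof},
        "chi2_ratio_one_step_over_if": ratio,
    }, indent=1))
    print(f"wrote {OUT / 'transient_fit.json'}")


if __name__ == "__main__":
    main()
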