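"""Static yield and Soderberg fatigue safety of the PEEK stem.

Evaluates the worked factor-of-safety values at the implant's measured
peak stresses (82.3 MPa medial neck, 76 MPa distal restriction point),
then maps yield and fatigue FoS over every stem element of the
synthetic field at the 2300 N peak of the R = 0.1 load cycle, and
exports the Soderberg-diagram coordinates for plotting.
"""

import argparse
from pathlib import Path

from ossishield import RunConfig
from ossishield._util import round_half_up
from ossishield.pipeline import generate_stage
from ossishield.safety import (
    cyclic_stresses,
    min_fos,
    safety_map,
    soderberg_fos,
    unsafe_fraction,
    yield_fos,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = RunConfig(seed=args.seed)
    params = cfg.fatigue

    print("Worked values at the measured peak stresses (PEEK, sigma_y 85.5 MPa):")
    print(f"  yield FoS @ 82.3 MPa (medial neck)  = {round_half_up(yield_fos(82.3, 85.5), 2):.2f}")
    print(f"  yield FoS @ 76.0 MPa (distal point) = {round_half_up(yield_fos(76.0, 85.5), 2):.2f}")
    sm, sa = cyclic_stresses(76.0, params)
    print(
        f"  cycle R = {params.stress_ratio_r}: sigma_m = {sm:.1f}, sigma_a = {sa:.1f} "
        f"-> Soderberg FoS = {round_half_up(soderberg_fos(sa, sm, params), 3):.3f}"
    )

    paired = generate_stage(cfg, "peek", cfg.analysis_load_n)
    smap = safety_map(paired.implanted, params, stem_material="peek")
    smap.to_csv(args.out_dir / "safety_peek.csv", index=False)
    smap[["element_id", "mean_stress_mpa", "alt_stress_mpa", "fos_soderberg"]].to_csv(
        args.out_dir / "soderberg_diagram_peek.csv", index=False
    )

    eid_y, fy = min_fos(smap, "fos_yield")
    eid_s, fs = min_fos(smap, "fos_soderberg")
    print(
        f"Synthetic stem field ({len(smap)} elements): min yield FoS {fy:.2f} "
        f"(element {eid_y}), min Soderberg FoS {fs:.2f} (element {eid_s}), "
        f"unsafe fraction {unsafe_fraction(smap):.2%}."
    )
    print(
        "Finding: the beam-scale stem field stays far from both limits; "
        "the critical locations are the neck stress concentrations, which "
        "enter through the measured peak stresses above."
    )


if __name__ == "__main__":
    main()
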