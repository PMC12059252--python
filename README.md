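# rgplan

Receiver-gain calibration and SNR-optimal acquisition planning for NMR.

## The problem

The receiver gain (RG) matches the NMR signal to the digitizer's dynamic
range. Automatic RG adjustment maximizes *signal* while avoiding ADC
overflow — but on several modern consoles the signal-to-noise ratio is
**not** monotone in RG: the receiver's internal gain staging (its "level
plan") switches abruptly near RG ~ 20 on low-frequency channels, and SNR
can drop by tens of percent just past the switch while the signal keeps
growing linearly. For hyperpolarized experiments (e.g. dissolution-DNP
[1-¹³C]pyruvate) the problem is acute: the signal is transient, automatic
gain adjustment is impossible, and a wrong guess either clips the FID
(ruining the spectrum) or throws away sensitivity.

`rgplan` implements the calibrate-once, plan-everything workflow:

1. **Calibrate.** Sweep RG on a thermally polarized reference sample at
   known flip angle α_ref, polarization P_ref and spin concentration
   C_ref; quantify each spectrum (peak integral, noise RMS of a
   signal-free region, maximum FID amplitude) into a reference curve
   SNR_ref(RG), using the linear signal model

       signal = A · f(RG) · sin α · P · C,        signal ≤ S_m ,

   where f(RG) is the receiver gain function (= RG for a linear receiver)
   and S_m = safety_factor · RRT is the maximum signal the ADC records
   faithfully (RRT = receiver range threshold).

2. **Rescale.** For any target sample,

       SNR(RG) = SNR_ref(RG) · sin α / sin α_ref · P/P_ref · C/C_ref .

3. **Plan.** Maximize SNR(RG, α) subject to the overflow constraint
   (predicted FID maximum ≤ S_m) and a flip-angle cap 0 < α ≤ α_m: build
   the signal and SNR maps on a dense (RG, α) grid, mask the overflow
   region, take the arg-max. The closed-form *clipping product*
   k = max sin α · RG and the flip-angle limit arcsin(k/RG) summarize the
   constraint for linear receivers.

A receiver-chain simulator (gain, input/output-referred noise with a
level-plan switch penalty, per-channel ADC clipping) generates every input
the pipeline needs, so the whole method is testable without a
spectrometer.

## Worked example

Emulate a 9.4 T-like ¹³C channel with a level-plan switch at RG 18, build
its calibration curve, and plan a hyperpolarized acquisition (90 mM ¹³C,
35 % polarization, flip angle capped at 5°, ADC ceiling 1.24·10⁹ a.u.):

```
$ rgplan simulate sweep --preset dip --amplitude 1e5 --sigma-in 4000 \
      --replicates 8 --seed 1 --out sweep.csv
wrote sweep.csv (15 RG settings)

$ rgplan -v calibrate --input sweep.csv --nucleus 13C --field-t 9.4 \
      --temperature-k 298 --alpha-ref-deg 90 --p-ref 8.105e-6 \
      --c-ref-mm 1308 --out-curve curve.csv --out-meta curve.json
rgplan: slope_integral=31982.2 a.u./(RG*M)
rgplan: slope_fid=80326.6 a.u./(RG*M)
rgplan: max |signal deviation| = 0.0219
rgplan: abrupt SNR drop after RG 18 (level-plan switch?)
wrote curve.csv (15 points) and curve.json

$ rgplan plan --calibration curve.csv --meta curve.json --conc-mm 90 \
      --pol 0.35 --alpha-max-deg 5 --rrt 1.24e9 --out plan.json
rg_opt=14 alpha_opt=5 deg snr_pred=2.636e+05 clip_margin=0.305
```

Reading the output: the calibration finds the two channel slopes (spectral
integral and FID maximum per RG and molar), a ≤ 2 % deviation from gain
linearity, and flags the abrupt SNR drop after RG 18. The plan lands in
the pre-switch plateau (RG 14, the largest flip angle allowed) and uses
only 30 % of the ADC ceiling — maximum sensitivity with a wide clipping
margin, instead of the maximum-gain setting an automatic adjustment would
pick.

The same machinery is available as a library (`rgplan.build_calibration`,
`rgplan.optimize`, `rgplan.flip_angle_limit`, `rgplan.normalize_series`,
...); see `docs/methods.md` for the model details.

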