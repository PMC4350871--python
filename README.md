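# ciliapump

Transport of a Casson (yield-stress) fluid driven by the metachronal
beating of cilia lining an axisymmetric tube — a lubrication-theory pump
model with exact wave-frame solutions, aimed at physiological transport
problems such as the movement of seminal fluid through the ciliated
ductus efferentes of the male reproductive tract.

## The model

The tips of the beating cilia are replaced by their envelope: a surface
wave of amplitude ε (cilia length relative to the mean radius *a*)
travelling at the metachronal wave speed *c*. In the frame moving with
the wave the wall is stationary,

    h(z) = 1 + ε cos 2πz,

with *z* in wavelengths, and imposes the no-slip velocities of the
elliptical tip paths (eccentricity α, wavenumber β = a/λ):

    w(h) = −1 − 2πεαβ cos 2πz,      u(h) = w(h) · dh/dz.

The fluid obeys the Casson law √τ = √τ₀ + √(μγ̇) above the yield stress
τ₀ and is rigid below it. In the long-wavelength, low-Reynolds
(lubrication) limit the shear stress is linear in radius, so an
unyielded plug of radius H_p = 2τ₀/|dp/dz| rides on the axis. The axial
velocity for r ≥ H_p is

    w = w(h) + (1/4)(dp/dz) [ (r−h)(r+h+2H_p) − (8/3)√H_p (r^{3/2} − h^{3/2}) ],

and the wave-frame flux q = 2∫₀ʰ r w dr has the closed form
q = h²w(h) − D(h,H_p) dp/dz with

    D(h, H_p) = (h⁴/8) [ 1 − (16/7) m^{1/2} + (4/3) m − m⁴/21 ],   m = H_p/h,

the classical Casson–Poiseuille bracket. Integrating dp/dz over one
wavelength gives the linear pump characteristic

    Δp = I₁ − q I₂,   I₁ = ∫₀¹ h²w(h)/D dz,   I₂ = ∫₀¹ dz/D,

with the time-mean flow rate Q̄ = q + 1 + ε²/2. From the characteristic
follow the free-pumping flux (Δp = 0 intercept), the threshold Q̄ above
which dp/dz is favorable everywhere, and the flow rate at which the
curves of two cilia lengths cross. The stream function ψ (radial
integral of the profile) yields wave-frame streamlines and the trapped
bolus — the region of closed streamlines carried bodily at the wave
speed — whose size shrinks with the plug width H_p and grows with ε.

## Worked example

```sh
ciliapump thresholds --eps 0.25 --alpha 0.4 --beta 0.4 --hp 0
```

```json
{
  "eps": 0.25, "alpha": 0.4, "beta": 0.4, "hp": 0.0,
  "i1": -8.259439788143503,
  "i2": 10.967523802712005,
  "free_pumping_flux": 0.2781684533612645,
  "favorable_gradient_threshold": 0.6101216694115408,
  "quadrature_points": 512
}
```

At this parameter set the pump delivers Q̄ ≈ 0.278 (in units of πa²c)
against zero pressure rise — the free-pumping flux — and the axial
pressure gradient becomes favorable at every station once Q̄ exceeds
0.610. The trapping census at the streamline-panel operating point:

```sh
ciliapump trapping --eps 0.25 --hp 0.05 --qbar 0.95
```

reports one trapped bolus of area 0.599 per wavelength with its
stagnation centre at (r, z) = (0.471, 0.5); rerunning with `--hp 0`
gives a larger bolus (0.607) — yield stress opposes trapping.

Other subcommands: `pump-curve`, `velocity-profile`, `flow-field`,
`ductus-report` (the physiological application, including the documented
gap between the solver's Q̄ and the published values), and
`figure <id>` (preset parameter sets of the published panels, `fig2a` …
`fig11`, emitting a backing CSV and a PNG).

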