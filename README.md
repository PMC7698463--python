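# voxfluor

Monte Carlo simulation of excitation and fluorescence-emission photon
migration in voxelized breast-tissue media.

Early ductal breast cancers of a few millimetres routinely escape
mammography and sonography.  Fluorescence molecular imaging in the
shortwave-infrared (SWIR, ~1000–2000 nm) promises deeper penetration and
lower scattering than visible (VIS) or near-infrared (NIR) imaging, but
whether a labeled cancer of a given size and depth produces a detectable
surface signal in a *human-scale* breast depends on the tissue's optical
properties and internal structure.  `voxfluor` answers that question
numerically, for researchers in biomedical optics and fluorescence-guided
diagnostics.

## Model

The breast is a 3-D grid of labeled voxels (air, skin, fat, duct, cancer);
each tissue carries per-wavelength optical properties (μa, μs, g, n).
Photons perform the standard weighted random walk of tissue Monte Carlo:
step lengths s = −ln ξ / μt, weight deposition μa/μt per interaction,
Henyey–Greenstein scattering with anisotropy g, unpolarized Fresnel
reflection/refraction at refractive-index mismatches, and Russian
roulette termination.  The per-voxel fluence is the collision estimate

    Φ[v] = A[v] · P / (N · μa[v] · V_voxel)       [W/cm²]

for deposited weight A, source power P and N launched photons.  The
fluorescence stage launches emission photons isotropically at uniform
random positions inside the cancer with initial weights proportional to
QY · εC · Φ_ex at the launch voxel (the *excitation gradient*; a legacy
mode uses the centre-voxel fluence uniformly), then transports them at the
emission wavelength.  Emission power escaping the tissue surface is binned
on the anterior projection; a cancer is **detectable** when the peak bin
exceeds 10 nW/cm², the sensitivity floor of fluorescence image sensors.

Three band/probe combinations ship in the optical tables: fluorescein
(Ex 488/Em 520 nm), indocyanine green (780/820 nm) and PbS quantum dots
(970/1100 nm).

Because the cryosection anatomy the reference geometry derives from is
not redistributable, the package includes a synthetic phantom generator
(contoured semi-ellipsoid breast, 2-voxel skin shell, branching duct tree
in fat) plus a grayscale-slice segmentation path for users who have their
own anatomical image stacks.

## Worked example

```python
import voxfluor as vf

phantom = vf.generate_breast_phantom(vf.PhantomParams(seed=1))
result = vf.run_fluorescence(
    phantom, "SWIR", vf.CancerSpec(diameter=1.0, depth=1.0),
    vf.SourceConfig(radius=1.0, irradiance=0.05),   # 50 mW/cm² disk beam
    vf.SimConfig(n_photons=20_000, seed=2),
)
det = vf.assess_detectability(vf.SurfaceMap.from_result(result))
print(f"peak {det.peak:.3e} W/cm2, detectable: {det.detectable}")
print(result.excitation.ledger.as_dict()["closure_residual"])
```

prints

```
peak 1.313e-05 W/cm2, detectable: True
2.502902762868246e-13
```

A 1 cm cancer at 1 cm depth returns a peak surface irradiance of
1.3 × 10⁻⁵ W/cm² in the SWIR — three orders of magnitude above the
10 nW/cm² sensor floor — and the run's weight ledger closes to machine
precision.  The same call with `"NIR"` gives roughly half that peak and
with `"VIS"` gives zero: visible excitation never reaches the cancer.

The same machinery is scriptable from the shell:

```bash
voxfluor phantom --out breast.nii.gz --seed 1
voxfluor simulate --volume breast.nii.gz --band swir \
    --cancer-diam 0.4 --cancer-depth 1.4 --photons 100000 --seed 7 --out run/
voxfluor sweep --config sweep.yaml --out table.tsv
```

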