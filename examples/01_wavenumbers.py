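"""Compute the propagation constants that drive lead-tip heating models.

Builds the lossy-medium (ASTM-gel), insulator and King wavenumbers for the
reference bench wire (a = 0.390 mm, b = 0.625 mm, silicone-like insulation)
at the 1.5 T proton Larmor frequency, and prints the guided wavelength.
"""

import leadheat as lh

F0 = 63.87e6  # Hz

medium = lh.MediumProperties(conductivity=0.47, relative_permittivity=80.0, frequency=F0)
re_kt, im_kt = lh.lossy_medium_wavenumber(medium)
print(f"gel wavenumber k_t      = {re_kt:.4f} - {im_kt:.4f}i rad/m")

k_i = lh.insulator_wavenumber(2.3, F0)
print(f"insulator wavenumber k_i = {k_i:.4f} rad/m")

xs = lh.InsulatedWireCrossSection(0.390e-3, 0.625e-3, 2.3)
k = lh.king_wavenumber(complex(re_kt, -im_kt), k_i, xs)
print(f"King wavenumber k        = {k.real:.4f} {k.imag:+.4f}i rad/m")

lam = lh.king_wavelength(k)
print(f"guided wavelength        = {lam * 100:.1f} cm (half: {lam * 50:.1f} cm)")

# Re(k) sets how fast the transfer-function phase winds along the wire
# (resonance when the wire length nears half a wavelength); Im(k) < 0 is the
# attenuation that makes extra path length - e.g. loops - reduce tip heating.
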