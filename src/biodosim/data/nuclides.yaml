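# Nuclide physical constants used by biodosim.
#
# Half-lives and mean emission energies per decay are taken from the ICRP
# Publication 107 decay-data compilation (rounded as below); edit or extend
# this file to add nuclides.
#
# mean_nonpenetrating_energy_kev: mean energy emitted per decay as electrons
#   (beta spectra mean + conversion/Auger electrons); positrons count as
#   electrons, their annihilation photons as penetrating radiation.
# photon_emissions: principal gamma/annihilation lines as [energy_kev, yield].
lu177:
  name: Lu-177
  half_life_h: 159.528          # 6.647 d
  mean_nonpenetrating_energy_kev: 147.9
  photon_emissions:
    - [208.366, 0.1038]
    - [112.950, 0.0620]
cu64:
  name: Cu-64
  half_life_h: 12.701
  mean_nonpenetrating_energy_kev: 121.0
  photon_emissions:
    - [511.0, 0.3520]           # annihilation
    - [1345.77, 0.00475]
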