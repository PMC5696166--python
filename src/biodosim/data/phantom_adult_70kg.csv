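# Reference adult phantom organ masses (grams) for a 70-kg standard human.
# Organ masses follow the Cristy-Eckerman adult hermaphrodite phantom
# (ORNL/TM-8381) with total blood mass from ICRP Publication 23; the body
# mass is normalised to the conventional 70 kg standard adult.
# Override with --phantom pointing at a file in this same format.
# body_mass_kg: 70.0
organ,mass_g
adrenals,16.3
blood,5500.0
bone,10000.0
brain,1420.0
breasts,351.0
heart,316.0
kidneys,299.0
large intestine,380.0
liver,1910.0
lungs,1000.0
muscle,28000.0
pancreas,94.3
skin,3010.0
small intestine,677.0
spleen,183.3
stomach,158.0
testes,39.1
thymus,20.9
thyroid,20.7
urinary bladder,47.6
uterus,79.0
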