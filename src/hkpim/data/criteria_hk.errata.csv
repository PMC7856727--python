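statement_id,field_name,printed_value,curated_value,rationale
IND073,atc_code_printed,N07BC02,N02BE01,Printed code is methadone's; the new-PIM section's codes are shifted against the drug names. Curated to the paracetamol substance code.
IND074,atc_code_printed,A06AG01,M02AC,Printed code is the sodium phosphate enema code. Curated to the topical salicylic-acid-derivative class.
IND075,atc_code_printed,A06AD15,N07BC02,Printed code is macrogol's. Curated to the methadone substance code.
IND076,atc_code_printed,M05BA,A06AG01,Printed code is the bisphosphonates class. Curated to the enema class covering sodium phosphate.
IND077,atc_code_printed,N02AA59,A06AD65,Printed code is a codeine-combination code. Curated to macrogol combinations (PEG electrolyte powder).
IND073,status,INCLUDED,INCLUDED,Listed in the final independent table although its median 3 fails the inclusion rule; the same statement also appears among the questionable statements (QIN004). Transcribed in both places as printed.
IND074,status,INCLUDED,INCLUDED,Listed in the final independent table although its median 3 fails the inclusion rule; duplicated as questionable statement QIN005. Transcribed in both places as printed.
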