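# Default event-of-interest dictionary: infection-related event classes,
# each defined as a set of MedDRA Preferred Terms (exact-string matching
# after trimming and case-folding).
Infection:
  - Arthritis infective
  - Aspergillus infection
  - Atypical mycobacterial infection
  - Cytomegalovirus infection
  - Epstein-Barr virus infection
  - Fungal infection
  - Infection
  - Infectious pleural effusion
  - Infective myositis
  - Mycobacterial infection
  - Mycobacterium avium complex infection
  - Mycobacterium marinum infection
  - Post procedural infection
  - Postoperative wound infection
  - Respiratory tract infection
  - Severe invasive streptococcal infection
  - Staphylococcal infection
  - Streptococcal infection
  - Urinary tract infection
  - Wound infection
Interstitial lung disease:
  - Interstitial lung disease
Pneumonia:
  - Eosinophilic pneumonia
  - Pneumonia
  - Pneumonia influenzal
  - Pneumonia mycoplasmal
  - Pneumonia pneumococcal
  - Pneumonia streptococcal
  - Pneumonia bacterial
  - Organising pneumonia
  - Atypical mycobacterial pneumonia
  - Pneumocystis jirovecii pneumonia
Sepsis:
  - Sepsis
  - Septic shock
  - Listeria sepsis
Tuberculosis:
  - Disseminated tuberculosis
  - Intestinal tuberculosis
  - Lymph node tuberculosis
  - Peritoneal tuberculosis
  - Pulmonary tuberculosis
  - Tuberculosis
  - Tuberculous pleurisy
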