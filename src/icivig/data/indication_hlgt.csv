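term,hlgt
Glioblastoma,Nervous system neoplasms malignant and unspecified NEC
Glioblastoma multiforme,Nervous system neoplasms malignant and unspecified NEC
Glioma,Nervous system neoplasms malignant and unspecified NEC
Malignant glioma,Nervous system neoplasms malignant and unspecified NEC
Astrocytoma,Nervous system neoplasms malignant and unspecified NEC
Astrocytoma malignant,Nervous system neoplasms malignant and unspecified NEC
Neuroblastoma,Nervous system neoplasms malignant and unspecified NEC
Medulloblastoma,Nervous system neoplasms malignant and unspecified NEC
Oligodendroglioma,Nervous system neoplasms malignant and unspecified NEC
Ependymoma,Nervous system neoplasms malignant and unspecified NEC
Brain neoplasm malignant,Nervous system neoplasms malignant and unspecified NEC
CNS neoplasm malignant,Nervous system neoplasms malignant and unspecified NEC
Melanoma,Skin neoplasms malignant and unspecified
Malignant melanoma,Skin neoplasms malignant and unspecified
Non-small cell lung cancer,Respiratory tract neoplasms
Breast cancer,Breast neoplasms malignant and unspecified
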