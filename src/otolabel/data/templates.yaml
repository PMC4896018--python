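# Sentence grammar for the synthetic temporal-bone report generator.
# "{meas}" marks an optional measurement slot filled as " measuring <value> <unit>".
history:
  - "Sensorineural hearing loss."
  - "Conductive hearing loss evaluation."
  - "Recurrent ear infections."
  - "Hearing loss since birth."
  - "Follow up of chronic ear disease."
  - "Mixed hearing loss."
impression_normal:
  - "Normal examination of the temporal bones."
  - "No acute abnormality of the temporal bones."
  - "Unremarkable temporal bone examination."
impression_abnormal:
  inner: "inner ear malformation as described above"
  middle: "middle ear disease as described above"
  outer: "external auditory canal abnormality as described above"
  mastoid: "mastoid opacification as described above"
regions:
  inner:
    abnormal:
      - "There is an enlarged vestibular aqueduct on the right{meas}."
      - "The cochlea demonstrates cochlear dysplasia consistent with mondini malformation."
      - "Dysplasia of the lateral semicircular canal is present."
      - "The vestibular aqueduct is enlarged bilaterally{meas}."
      - "Labyrinthine ossification involves the basal turn of the cochlea."
      - "There is cochlear nerve deficiency on the left."
      - "The vestibule is dilated and dysplastic."
      - "Abnormal semicircular canal morphology is identified."
      - "Incomplete partition of the cochlea is noted."
      - "Vestibular aqueduct enlargement is again demonstrated{meas}."
    negated:
      - "There is no enlargement of the vestibular aqueduct."
      - "No cochlear dysplasia is identified."
      - "The semicircular canals show no dysplasia."
      - "No labyrinthine ossification is seen."
      - "There is no enlarged vestibular aqueduct."
      - "No abnormality of the vestibule or semicircular canals."
      - "The cochlea shows no malformation."
      - "No cochlear nerve deficiency is evident."
    benign:
      - "The cochlea is intact."
      - "The vestibule and semicircular canals are unremarkable."
      - "The cochlea and vestibular aqueduct appear normal."
      - "Normal appearance of the semicircular canals."
  middle:
    abnormal:
      - "There is ossicular erosion involving the incus."
      - "A cholesteatoma fills the epitympanum."
      - "Tympanic membrane perforation is present."
      - "There is ossicular chain disruption."
      - "Soft tissue in the middle ear with erosion of the ossicles."
      - "The stapes demonstrates fixation."
      - "Erosion of the scutum is identified."
      - "The malleus and incus are eroded."
      - "Middle ear effusion with ossicular erosion is seen{meas}."
      - "Retraction of the tympanic membrane with erosion of the incus."
    negated:
      - "There is no ossicular erosion."
      - "No cholesteatoma is identified."
      - "The tympanic membrane shows no perforation."
      - "No erosion of the ossicles."
      - "There is no middle ear effusion."
      - "No ossicular chain disruption is seen."
      - "The stapes shows no fixation."
      - "No erosion of the scutum."
    benign:
      - "The ossicles are intact."
      - "The tympanic membrane is unremarkable."
      - "The malleus incus and stapes appear normal."
      - "The middle ear is well aerated."
  outer:
    abnormal:
      - "There is atresia of the external auditory canal."
      - "Canal atresia is present on the right."
      - "The external auditory canal demonstrates stenosis{meas}."
      - "Soft tissue opacifies the external auditory canal."
      - "There is canal stenosis with narrowing{meas}."
      - "Aural atresia with absent canal is identified."
      - "Exostosis narrows the external auditory canal."
      - "A bony atresia plate replaces the external auditory canal."
    negated:
      - "There is no atresia of the external auditory canal."
      - "No canal stenosis is identified."
      - "The external auditory canal shows no stenosis."
      - "No soft tissue within the external auditory canal."
      - "No aural atresia is seen."
      - "No exostosis of the canal."
    benign:
      - "The external auditory canal is patent."
      - "The external auditory canals are normal in caliber."
      - "Patent external auditory canal bilaterally."
  mastoid:
    abnormal:
      - "There is mastoid opacification on the left."
      - "Opacification of the mastoid air cells is present."
      - "Findings consistent with coalescent mastoiditis."
      - "The mastoid air cells are opacified with effusion."
      - "Sclerotic mastoid with loss of air cells."
      - "Mastoid effusion is identified{meas}."
      - "There is mastoiditis with trabecular breakdown."
      - "Extensive mastoid air cell opacification is seen."
    negated:
      - "There is no mastoid opacification."
      - "No opacification of the mastoid air cells."
      - "The mastoid air cells show no effusion."
      - "No mastoiditis is identified."
      - "No mastoid effusion."
    benign:
      - "The mastoid air cells are clear."
      - "The mastoids are well aerated."
      - "Clear mastoid air cells bilaterally."
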