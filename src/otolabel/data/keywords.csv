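region,keyword
inner,enlarged vestibular aqueduct
inner,vestibular aqueduct enlargement
inner,cochlear dysplasia
inner,cochlear malformation
inner,incomplete partition
inner,mondini
inner,semicircular canal dysplasia
inner,labyrinthine ossification
inner,cochlear nerve deficiency
inner,dilated vestibule
middle,ossicular erosion
middle,ossicular chain disruption
middle,cholesteatoma
middle,tympanic membrane perforation
middle,erosion of the ossicles
middle,erosion of the incus
middle,erosion of the scutum
middle,stapes fixation
middle,middle ear effusion
outer,canal atresia
outer,aural atresia
outer,atresia
outer,canal stenosis
outer,external auditory canal stenosis
outer,exostosis
mastoid,mastoid opacification
mastoid,mastoiditis
mastoid,mastoid effusion
mastoid,opacification of the mastoid
mastoid,sclerotic mastoid
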