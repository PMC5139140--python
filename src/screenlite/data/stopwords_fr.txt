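# French stopword profile for language detection
le de un être et à il avoir ne je son que se qui ce dans en du elle au
pour pas vous par sur faire plus dire me on mon lui nous comme mais
avec tout y aller voir bien où sans tu ou leur si deux mari moi vouloir
te femme venir quand grand celui des les une cette ces est sont était
étaient chez entre contre après avant aussi donc car cet été très
étude résultats patients études
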